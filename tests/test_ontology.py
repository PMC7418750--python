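"""Terminology normalization, type distributions, ranking, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontolabel.corpus import doc_from_sentences
from ontolabel.ontology import (
    REJECT,
    Terminology,
    build_type_distribution,
    load_terminology,
    match_key,
    normalize_term,
    partition_sources,
    rank_by_coverage,
    save_terminology_tsv,
)


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Aspirin", ("aspirin",)),
            ("DMD", ("DMD",)),  # abbreviation keeps case
            ("Heart Failure", ("heart", "failure")),
            ("EGFR status", ("EGFR", "status")),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_term(raw) == expected

    @pytest.mark.parametrize("raw", ["a", "42", "the", "3.5"])
    def test_rejects_stopwords_numbers_single_chars(self, raw):
        assert normalize_term(raw) is REJECT

    def test_multi_token_with_number_kept(self):
        assert normalize_term("diabetes type 2") == ("diabetes", "type", "2")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            normalize_term("  ")

    def test_match_key_mixed_case_heuristic(self):
        assert match_key("HbA1c") == "HbA1c"  # >= 2 uppercase, short
        assert match_key("Aspirin") == "aspirin"
        assert match_key("INSULIN") == "insulin"  # too long to be an abbreviation


class TestLoadTerminology:
    def write(self, tmp_path, rows):
        p = tmp_path / "t.tsv"
        p.write_text("term\tsource\tsemantic_type\n" + "".join(f"{t}\t{s}\t{y}\n" for t, s, y in rows))
        return p

    def test_stopword_row_dropped(self, tmp_path):
        p = self.write(tmp_path, [("aspirin", "V", "drug"), ("the", "V", "drug"), ("insulin", "V", "drug")])
        term = load_terminology(p, {"drug": 1})
        assert len(term) == 2 and term.name == "V"

    def test_term_with_two_types_is_one_entry(self, tmp_path):
        p = self.write(tmp_path, [("lead", "V", "chem"), ("lead", "V", "finding")])
        term = load_terminology(p, {"chem": 1, "finding": 2})
        assert term.entries[("lead",)] == {1, 2}

    def test_unmapped_and_ignored_types_dropped(self, tmp_path):
        p = self.write(tmp_path, [("aspirin", "V", "drug"), ("foo", "V", "junk"), ("bar", "V", "skip")])
        term = load_terminology(p, {"drug": 1, "skip": -1})
        assert set(term.entries) == {("aspirin",)}

    def test_empty_file_warns(self, tmp_path, caplog):
        p = self.write(tmp_path, [])
        with caplog.at_level("WARNING"):
            term = load_terminology(p, {"drug": 1})
        assert len(term) == 0 and any("empty" in r.message for r in caplog.records)

    def test_missing_columns_error_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("term\tsource\tsemantic_type\naspirin\tV\n")
        with pytest.raises(ValueError, match=":2"):
            load_terminology(p, {"drug": 1})

    def test_json_format(self, tmp_path):
        p = tmp_path / "t.json"
        p.write_text('{"name": "J", "entries": [{"term": "aspirin", "types": ["drug"]}]}')
        term = load_terminology(p, {"drug": 1})
        assert term.name == "J" and ("aspirin",) in term.entries

    def test_tsv_round_trip(self, tmp_path):
        t = Terminology("V")
        t.add(("aspirin",), {1})
        t.add(("heart", "failure"), {2})
        p = tmp_path / "v.tsv"
        save_terminology_tsv(t, p)
        back = load_terminology(p, {"1": 1, "2": 2})
        assert back.entries == t.entries


class TestTypeDistribution:
    def make(self, assignments, n_classes=3):
        terms = []
        for i, classes in enumerate(assignments):
            t = Terminology(f"s{i}")
            t.add(("x",), set(classes))
            terms.append(t)
        return build_type_distribution(terms, n_classes)

    def test_unanimous_source_gives_point_mass(self):
        m = self.make([[1], [1], [1]])
        assert m.vector(("x",))[1] == 1.0

    def test_two_vs_one_gives_two_thirds(self):
        m = self.make([[1], [1], [2]])
        assert np.allclose(m.vector(("x",)), [0, 2 / 3, 1 / 3])

    def test_exact_tie_is_flagged(self):
        m = self.make([[1], [2]])
        cls, tie = m.most_probable(("x",))
        assert tie

    def test_vectors_sum_to_one(self, small_world):
        from ontolabel.synthetic import SourceSpec, generate_sources

        sources = generate_sources(small_world, [SourceSpec(recall=0.7, name=f"s{i}") for i in range(3)])
        m = build_type_distribution(sources, 2)
        for term in m.counts:
            assert abs(m.vector(term).sum() - 1.0) < 1e-9


class TestRanking:
    def docs(self, sents):
        return [doc_from_sentences(f"d{i}", [s]) for i, s in enumerate(sents)]

    def term_of(self, name, *words):
        t = Terminology(name)
        for w in words:
            t.add((w,), {1})
        return t

    def test_higher_document_frequency_ranks_first(self):
        corpus = self.docs([["apixaban"], ["apixaban"], ["apixaban"], ["heparin"], ["filler"]])
        a = self.term_of("A", "apixaban")
        b = self.term_of("B", "heparin")
        assert [t.name for t in rank_by_coverage([b, a], corpus)] == ["A", "B"]

    def test_empty_corpus_alphabetical(self):
        a, b = self.term_of("zeta", "x"), self.term_of("alpha", "y")
        assert [t.name for t in rank_by_coverage([a, b], [])] == ["alpha", "zeta"]

    def test_matches_brute_force_document_scan(self, small_world):
        """Coverage score equals a per-document membership count computed
        naively on a 10-document toy corpus."""
        from ontolabel.synthetic import SourceSpec, generate_corpus, generate_sources

        docs, _, _ = generate_corpus(small_world, 20, sents_per_doc=2, seed=5)
        docs = docs[:10]
        sources = generate_sources(small_world, [SourceSpec(recall=0.5, name=f"s{i}") for i in range(2)], seed=6)
        # brute force: single-token terms counted by document membership
        scores = {}
        for src in sources:
            single = {t[0] for t in src.terms() if len(t) == 1}
            multi = [t for t in src.terms() if len(t) > 1]
            score = 0
            for doc in docs:
                toks = [tok for s in doc.sentences for tok in s.tokens]
                hit_terms = {w for w in single if w in toks}
                joined = " ".join(toks)
                hit_terms |= {t for t in multi if " ".join(t) in joined}
                score += len(hit_terms)
            scores[src.name] = score
        ranked = rank_by_coverage(sources, docs)
        assert [t.name for t in ranked] == [
            t.name for t in sorted(sources, key=lambda v: (-scores[v.name], v.name))
        ]

    def test_invariant_to_document_order(self, small_world, small_corpus):
        from ontolabel.synthetic import SourceSpec, generate_sources

        docs, _, _ = small_corpus
        sources = generate_sources(small_world, [SourceSpec(recall=0.6, name=f"s{i}") for i in range(3)])
        fwd = [t.name for t in rank_by_coverage(sources, docs)]
        rev = [t.name for t in rank_by_coverage(sources, docs[::-1])]
        assert fwd == rev


class TestPartition:
    def sources(self, n):
        out = []
        for i in range(n):
            t = Terminology(f"s{i}")
            t.add((f"term{i}",), {1})
            t.add(("shared",), {1})
            out.append(t)
        return out

    def test_top_s_plus_merged(self):
        part = partition_sources(self.sources(4), 2)
        assert len(part.individual_sources) == 2
        assert len(part.label_sources()) == 3

    def test_s_equals_total_omits_merged(self):
        part = partition_sources(self.sources(3), 3)
        assert part.merged_remainder is None and len(part.label_sources()) == 3

    def test_s_one(self):
        part = partition_sources(self.sources(4), 1)
        assert len(part.label_sources()) == 2

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            partition_sources(self.sources(3), 0)
        with pytest.raises(ValueError):
            partition_sources(self.sources(3), 4)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6))
    def test_every_term_covered_exactly_once(self, n, s):
        """Conservation: each input term appears in exactly one label source."""
        if s > n:
            return
        srcs = self.sources(n)
        part = partition_sources(srcs, s)
        all_terms = set().union(*(t.terms() for t in srcs))
        covered = set().union(*(t.terms() for t in part.label_sources()))
        assert covered == all_terms
        # individual sources are disjoint from the merged remainder's extras
        indiv = set().union(*(t.terms() for t in part.individual_sources))
        if part.merged_remainder is not None:
            merged_only = part.merged_remainder.terms() - {("shared",)}
            assert not (merged_only & (indiv - {("shared",)}))
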