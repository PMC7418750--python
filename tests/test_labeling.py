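"""Labeling-function templates and label-matrix construction."""

import datetime

import numpy as np
import pytest

from ontolabel.corpus import Span, doc_from_sentences
from ontolabel.labeling import (
    ContextWindowLF,
    CuePattern,
    LabelMatrix,
    PatternLF,
    SemanticTypeLF,
    Synset,
    SynsetLF,
    build_label_matrix,
    build_span_label_matrix,
    parse_date_at,
    schwartz_hearst_pairs,
)
from ontolabel.ontology import Terminology, build_type_distribution


def make_lf(entries, unmatched="abstain", n_classes=3, name="onto"):
    t = Terminology(name)
    for term, classes in entries.items():
        t.add(term, set(classes))
    return SemanticTypeLF(name, t, build_type_distribution([t], n_classes), unmatched=unmatched)


def sent(*tokens, doc_id="d"):
    return doc_from_sentences(doc_id, [list(tokens)]).sentences[0]


class TestSemanticTypeLF:
    def test_longest_match_disambiguates_nested_terms(self):
        # "lung" alone is anatomy (class 2); "lung cancer" is disease (class 1)
        lf = make_lf({("lung",): {2}, ("lung", "cancer"): {1}})
        vec = lf.label_sequence(sent("the", "lung", "cancer", "case"))
        assert vec.tolist() == [-1, 1, 1, -1]

    def test_no_match_uses_unmatched_policy(self):
        lf_abstain = make_lf({("aspirin",): {1}})
        lf_negative = make_lf({("aspirin",): {1}}, unmatched="negative")
        s = sent("no", "terms", "here")
        assert lf_abstain.label_sequence(s).tolist() == [-1, -1, -1]
        assert lf_negative.label_sequence(s).tolist() == [0, 0, 0]

    def test_exact_type_tie_abstains_on_match(self):
        ta = Terminology("a")
        ta.add(("lead",), {1})
        tb = Terminology("b")
        tb.add(("lead",), {2})
        lf = SemanticTypeLF("ab", ta.merged_with(tb), build_type_distribution([ta, tb], 3))
        assert lf.label_sequence(sent("lead", "exposure")).tolist() == [-1, -1]

    def test_case_insensitive_except_abbreviations(self):
        lf = make_lf({("aspirin",): {1}, ("DMD",): {1}})
        assert lf.label_sequence(sent("Aspirin", "helps")).tolist() == [1, -1]
        # lowercase "dmd" must not match the abbreviation entry
        assert lf.label_sequence(sent("dmd", "DMD")).tolist() == [-1, 1]


class TestSlotPatterns:
    def test_paren_pattern_labels_whole_region(self):
        lf = make_lf({("tylenol",): {1}, ("acetaminophen",): {1}})
        vec = lf.label_sequence(sent("Tylenol", "(", "Acetaminophen", ")", "given"))
        assert vec.tolist() == [1, 1, 1, 1, -1]

    def test_pattern_requires_both_slots_in_ontology(self):
        lf = make_lf({("tylenol",): {1}})
        vec = lf.label_sequence(sent("Tylenol", "(", "hello", ")"))
        assert vec.tolist() == [1, -1, -1, -1]

    def test_pattern_slots_must_agree_on_class(self):
        lf = make_lf({("tylenol",): {1}, ("lung",): {2}})
        vec = lf.label_sequence(sent("Tylenol", "(", "lung", ")"))
        assert vec.tolist() == [1, -1, 2, -1]

    def test_longer_plain_match_beats_nested_pattern(self):
        lf = make_lf(
            {
                ("aa",): {1},
                ("bb",): {1},
                # 5-token term covering the whole pattern region and one more
                ("aa", "(", "bb", ")", "cc"): {2},
            }
        )
        vec = lf.label_sequence(sent("aa", "(", "bb", ")", "cc"))
        assert vec.tolist() == [2, 2, 2, 2, 2]


class TestSynsetLF:
    synsets = [Synset("C1", {("duchenne", "muscular", "dystrophy"), ("DMD",)}, 1)]

    def test_fires_with_two_distinct_members(self):
        doc = doc_from_sentences(
            "d", [["duchenne", "muscular", "dystrophy", "confirmed"], ["DMD", "progressing"]]
        )
        vecs = SynsetLF("syn", self.synsets).label_document(doc)
        assert vecs[0].tolist() == [1, 1, 1, -1]
        assert vecs[1].tolist() == [1, -1]

    def test_single_member_abstains(self):
        doc = doc_from_sentences("d", [["DMD", "progressing"]])
        vecs = SynsetLF("syn", self.synsets).label_document(doc)
        assert vecs[0].tolist() == [-1, -1]

    def test_adding_text_never_removes_a_firing(self):
        base = [["duchenne", "muscular", "dystrophy"], ["DMD"]]
        more = base + [["unrelated", "words"], ["DMD", "again"]]
        lf = SynsetLF("syn", self.synsets)
        v_base = lf.label_document(doc_from_sentences("d", base))
        v_more = lf.label_document(doc_from_sentences("d", more))
        for vb, vm in zip(v_base, v_more):
            assert ((vb != -1) <= (vm != -1)).all()

    def test_schwartz_hearst_links_out_of_dictionary_abbreviation(self):
        doc = doc_from_sentences(
            "d",
            [["heart", "failure", "(", "HF", ")", "noted"], ["HF", "worsening"]],
        )
        synsets = [Synset("C2", {("heart", "failure"), ("cardiac", "failure")}, 1)]
        vecs = SynsetLF("syn", synsets, schwartz_hearst=True).label_document(doc)
        assert vecs[0].tolist() == [1, 1, -1, 1, -1, -1]
        assert vecs[1].tolist() == [1, -1]  # later occurrence labeled

    def test_schwartz_hearst_pair_extraction(self):
        doc = doc_from_sentences("d", [["chronic", "heart", "failure", "(", "CHF", ")"]])
        pairs = schwartz_hearst_pairs(doc)
        assert (("chronic", "heart", "failure"), ("CHF",)) in pairs


class TestContextWindowLF:
    def doc_with_entity(self, tokens, start, end, timestamp=None):
        doc = doc_from_sentences("d", [tokens], timestamp=timestamp)
        return doc, [Span("d", 0, start, end, 1)]

    def test_left_window_negation_cue(self):
        doc, spans = self.doc_with_entity(["no", "evidence", "of", "pneumonia"], 3, 4)
        lf = ContextWindowLF("negex", [CuePattern("left", 4, "no evidence of", 1)])
        assert lf.label_spans(doc, spans).tolist() == [1]

    def test_no_trigger_abstains(self):
        doc, spans = self.doc_with_entity(["patient", "has", "pneumonia"], 2, 3)
        lf = ContextWindowLF("negex", [CuePattern("left", 3, "no evidence of", 1)])
        assert lf.label_spans(doc, spans).tolist() == [-1]

    def test_nearest_datetime_determines_relation(self):
        # event at token 10; dates at tokens 5 and 30; nearest (token 5) is
        # older than the document date -> "before"
        tokens = ["w"] * 40
        tokens[5] = "2020-01-01"
        tokens[30] = "2020-06-01"
        tokens[10] = "event"
        doc, spans = self.doc_with_entity(tokens, 10, 11, timestamp=datetime.date(2020, 3, 15))
        lf = ContextWindowLF("dtr", datetime_labels={"before": 1, "after": 2, "overlap": 3})
        assert lf.label_spans(doc, spans).tolist() == [1]

    def test_missing_timestamp_abstains(self, caplog):
        tokens = ["w"] * 8
        tokens[2] = "2020-01-01"
        doc, spans = self.doc_with_entity(tokens, 4, 5, timestamp=None)
        lf = ContextWindowLF("dtr", datetime_labels={"before": 1})
        with caplog.at_level("WARNING"):
            assert lf.label_spans(doc, spans).tolist() == [-1]

    @pytest.mark.parametrize(
        "tokens,i,expected",
        [
            (["2021-07-04"], 0, datetime.date(2021, 7, 4)),
            (["3/15/2020"], 0, datetime.date(2020, 3, 15)),
            (["March", "5", ",", "2020"], 0, datetime.date(2020, 3, 5)),
            (["March", "5,", "2020"], 0, datetime.date(2020, 3, 5)),
            (["13/45/2020"], 0, None),
        ],
    )
    def test_date_parsing_dialects(self, tokens, i, expected):
        assert parse_date_at(tokens, i) == expected


class TestPatternLF:
    def test_punctuation_dictionary_emits_negative_class(self):
        lf = PatternLF("punct", label=0, dictionary={(",",), (".",)})
        assert lf.label_sequence(sent("mild", ",", "dry")).tolist() == [-1, 0, -1]

    def test_regex_dose_pattern(self):
        lf = PatternLF("dose", label=2, regex=r"[0-9]+ ?mg")
        assert lf.label_sequence(sent("500", "mg", "daily")).tolist() == [2, 2, -1]

    def test_no_match_all_abstain(self):
        lf = PatternLF("dose", label=2, regex=r"xyz")
        assert lf.label_sequence(sent("a1", "b1")).tolist() == [-1, -1]

    def test_invalid_regex_is_a_load_time_error(self):
        with pytest.raises(ValueError, match="invalid regex"):
            PatternLF("bad", label=1, regex="([")


class TestLabelMatrix:
    def test_single_lf_shape(self):
        lf = make_lf({("aspirin",): {1}})
        docs = [doc_from_sentences("d", [["aspirin", "po", "daily", "prn"]])]
        matrix = build_label_matrix([lf], docs)
        assert matrix.values.shape == (4, 1)
        assert matrix.row_index[0] == ("d", 0, 0)

    def test_duplicate_names_rejected(self):
        lf = make_lf({("aspirin",): {1}})
        with pytest.raises(ValueError, match="duplicate"):
            build_label_matrix([lf, lf], [doc_from_sentences("d", [["x"]])])

    def test_abstain_only_column(self):
        lf = make_lf({("nothing_matches",): {1}})
        docs = [doc_from_sentences("d", [["a1", "b1", "c1"]])]
        matrix = build_label_matrix([lf], docs)
        assert (matrix.values == -1).all()

    def test_partial_coverage_disagreement(self):
        """Sources lacking the full multi-token term disagree word-by-word
        with those that have it."""
        from ontolabel.synthetic import span_disagreement_fixture

        docs, terms, gold, k = span_disagreement_fixture()
        lfs = [
            SemanticTypeLF(t.name, t, build_type_distribution([t], k), unmatched="negative")
            for t in terms
        ]
        matrix = build_label_matrix(lfs, docs)
        # full-term sources label all three tokens; partial ones only "diabetes"
        assert matrix.values[3:6, 0].tolist() == [1, 1, 1]
        assert matrix.values[3:6, 2].tolist() == [1, 0, 0]

    def test_save_load_round_trip(self, tmp_path):
        lf = make_lf({("aspirin",): {1}})
        docs = [doc_from_sentences("d", [["aspirin", "daily"]])]
        matrix = build_label_matrix([lf], docs)
        matrix.save(tmp_path / "m")
        back = LabelMatrix.load(tmp_path / "m")
        assert (back.values == matrix.values).all()
        assert back.row_index == matrix.row_index
        assert back.lf_names == matrix.lf_names

    def test_span_matrix(self):
        doc = doc_from_sentences("d", [["no", "cough", "noted"]])
        spans = {"d": [Span("d", 0, 1, 2, 1)]}
        lf = ContextWindowLF("neg", [CuePattern("left", 2, "no", 1)])
        matrix = build_span_label_matrix([lf], [doc], spans)
        assert matrix.values.tolist() == [[1]]


class TestProperties:
    def test_term_insertion_order_invariance(self):
        entries = {("lung", "cancer"): {1}, ("lung",): {2}, ("cancer",): {1}}
        lf_a = make_lf(entries)
        lf_b = make_lf(dict(reversed(list(entries.items()))))
        s = sent("lung", "cancer", "and", "lung")
        assert lf_a.label_sequence(s).tolist() == lf_b.label_sequence(s).tolist()

    def test_label_vector_length_always_matches(self, small_world, small_corpus):
        from ontolabel.synthetic import SourceSpec, generate_sources

        docs, _, _ = small_corpus
        (src,) = generate_sources(small_world, [SourceSpec(recall=0.5)])
        lf = SemanticTypeLF("s", src, build_type_distribution([src], 2))
        for doc in docs[:10]:
            for vec, s in zip(lf.label_document(doc), doc.sentences):
                assert len(vec) == len(s)
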