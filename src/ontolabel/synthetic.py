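"""Seeded generators for corpora, terminologies, and raw label matrices with
known ground truth.

These stand in for license-gated ontologies and clinical corpora: sentences
are background words with entity terms (from a generating lexicon with
multi-token entries and synonym groups) inserted at a controlled density,
and label sources have controlled recall (fraction of the lexicon known),
spurious-term inclusion, and type-assignment error. Entity tokens carry a
characteristic morphology (class-specific suffixes, disjoint from background
words), emulating biomedical nomenclature, so that character features can
generalize to held-out lexicon entries. All generators are pure functions of
their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import IO, Document, Span, TagSequence, doc_from_sentences, spans_to_tags
from .labeling import LabelMatrix, Synset
from .ontology import Terminology

_ENTITY_STEMS = [
    "flor", "zan", "quel", "dov", "mira", "tex", "bol", "ner", "gad", "pex",
    "rov", "sil", "tam", "vex", "lor", "kan", "jus", "hax", "fen", "dal",
]
_CLASS_SUFFIXES = {
    1: ["mab", "nib", "pril", "oxin", "azole"],
    2: ["itis", "osis", "emia", "opathy"],
    3: ["gram", "scopy", "plasty"],
    4: ["cyte", "blast"],
}
_BG_SYLLABLES = [
    "ta", "re", "lo", "mi", "su", "ne", "va", "ko", "pi", "du",
    "we", "ga", "hu", "se", "ba", "ro", "li", "mo", "te", "na",
]


@dataclass
class WorldSpec:
    """The generating conditions for a synthetic labeling world."""

    n_classes: int = 2  # total classes including the negative class 0
    lexicon_size: int = 60  # entity terms per positive class
    multi_token_frac: float = 0.3  # 2-3 token entries
    synonym_frac: float = 0.2  # entries with an abbreviation synonym
    background_vocab_size: int = 300
    entity_density: float = 0.5  # P(sentence contains an entity)
    sent_len_range: tuple[int, int] = (6, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.entity_density <= 1.0:
            raise ValueError("entity_density must be in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least one entity class")


@dataclass
class SourceSpec:
    """Quality knobs for one synthetic label source.

    ``bg_coverage`` is the fraction of the background vocabulary the source
    knows and correctly maps to the negative class — the analogue of an
    ontology whose semantic-type map sends non-target concepts to y = 0.
    """

    recall: float = 1.0  # fraction of the lexicon the source knows
    spurious_rate: float = 0.0  # spurious background terms / known terms
    type_error_rate: float = 0.0  # P(term assigned a wrong class)
    bg_coverage: float = 0.0  # fraction of background vocab known as class 0
    name: str = ""

    def __post_init__(self) -> None:
        for r in (self.recall, self.type_error_rate, self.bg_coverage):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")


@dataclass
class World:
    spec: WorldSpec
    lexicon: dict[int, list[tuple[str, ...]]]  # class -> entity terms
    synonyms: dict[str, tuple[set[tuple[str, ...]], int]]  # concept -> (terms, class)
    background: list[str]

    def all_terms(self) -> dict[tuple[str, ...], int]:
        return {t: c for c, terms in self.lexicon.items() for t in terms}

    def synsets(self) -> list[Synset]:
        return [Synset(cid, set(terms), cls) for cid, (terms, cls) in sorted(self.synonyms.items())]


def build_world(spec: WorldSpec) -> World:
    rng = np.random.default_rng(spec.seed)
    used: set[str] = set()

    def entity_word(cls: int) -> str:
        for _ in range(1000):
            stem = "".join(rng.choice(_ENTITY_STEMS, size=rng.integers(1, 3)))
            w = stem + str(rng.choice(_CLASS_SUFFIXES.get(cls, _CLASS_SUFFIXES[1])))
            if w not in used:
                used.add(w)
                return w
        raise RuntimeError("entity vocabulary exhausted")

    lexicon: dict[int, list[tuple[str, ...]]] = {}
    synonyms: dict[str, tuple[set[tuple[str, ...]], int]] = {}
    for cls in range(1, spec.n_classes):
        terms: list[tuple[str, ...]] = []
        for i in range(spec.lexicon_size):
            n_tok = 1
            if rng.random() < spec.multi_token_frac:
                n_tok = int(rng.integers(2, 4))
            term = tuple(entity_word(cls) for _ in range(n_tok))
            terms.append(term)
            if rng.random() < spec.synonym_frac:
                abbrev = ("".join(w[0] for w in term).upper() + str(len(terms)),)
                synonyms[f"C{cls}_{i}"] = ({term, abbrev}, cls)
        lexicon[cls] = terms

    background: list[str] = []
    while len(background) < spec.background_vocab_size:
        w = "".join(rng.choice(_BG_SYLLABLES, size=rng.integers(2, 4)))
        if w not in used and w not in background:
            background.append(w)
    return World(spec, lexicon, synonyms, background)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(
    world: World,
    n_sentences: int,
    sents_per_doc: int = 5,
    seed: int | None = None,
    term_pool: dict[tuple[str, ...], int] | None = None,
) -> tuple[list[Document], dict[str, list[Span]], dict[tuple[str, int], TagSequence]]:
    """Sample sentences of background words, inserting one entity term with
    probability ``entity_density``; gold spans and IO tags are recorded.

    ``term_pool`` restricts which lexicon entries appear (e.g. a held-out
    subset); default is the full lexicon.
    """
    spec = world.spec
    pool = term_pool if term_pool is not None else world.all_terms()
    if not pool and spec.entity_density > 0:
        raise ValueError("empty entity lexicon with positive density")
    terms = sorted(pool)
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    docs: list[Document] = []
    gold_spans: dict[str, list[Span]] = {}
    gold_tags: dict[tuple[str, int], TagSequence] = {}
    sents: list[list[str]] = []
    spans_buf: list[tuple[int, int, int, int]] = []  # sent_idx, start, end, cls

    def flush() -> None:
        doc_id = f"doc{len(docs):05d}"
        doc = doc_from_sentences(doc_id, sents.copy())
        docs.append(doc)
        gold_spans[doc_id] = [Span(doc_id, si, s, e, c) for si, s, e, c in spans_buf]
        for sent in doc.sentences:
            in_sent = [sp for sp in gold_spans[doc_id] if sp.sent_index == sent.sent_index]
            gold_tags[(doc_id, sent.sent_index)] = spans_to_tags(in_sent, sent, IO)
        sents.clear()
        spans_buf.clear()

    for i in range(n_sentences):
        length = int(rng.integers(spec.sent_len_range[0], spec.sent_len_range[1] + 1))
        toks = [world.background[j] for j in rng.integers(0, len(world.background), size=length)]
        si = len(sents)
        if terms and rng.random() < spec.entity_density:
            term = terms[int(rng.integers(0, len(terms)))]
            cls = pool[term]
            pos = int(rng.integers(0, length + 1))
            toks = toks[:pos] + list(term) + toks[pos:]
            spans_buf.append((si, pos, pos + len(term), cls))
        sents.append(toks)
        if len(sents) == sents_per_doc or i == n_sentences - 1:
            flush()
    return docs, gold_spans, gold_tags


# ---------------------------------------------------------------------------
# Source generation
# ---------------------------------------------------------------------------


def generate_sources(world: World, specs: list[SourceSpec], seed: int | None = None) -> list[Terminology]:
    """Materialize noisy terminologies: each samples a recall fraction of
    the true lexicon, adds spurious background terms, and corrupts type
    assignments at the stated rate. Deterministic given the seed."""
    if not specs:
        raise ValueError("need at least one source spec")
    rng = np.random.default_rng(world.spec.seed + 1 if seed is None else seed)
    wrong = lambda c: int(rng.choice([k for k in range(1, world.spec.n_classes) if k != c])) \
        if world.spec.n_classes > 2 else c
    out = []
    all_terms = sorted(world.all_terms().items())
    for idx, spec in enumerate(specs):
        term = Terminology(spec.name or f"src{idx}")
        n_known = max(1, round(spec.recall * len(all_terms)))
        known_idx = rng.choice(len(all_terms), size=n_known, replace=False)
        for i in sorted(known_idx):
            t, cls = all_terms[i]
            if spec.type_error_rate and rng.random() < spec.type_error_rate:
                cls = wrong(cls) if world.spec.n_classes > 2 else 0
            term.add(t, {cls})
        n_spurious = round(spec.spurious_rate * n_known)
        if n_spurious:
            picks = rng.choice(len(world.background), size=min(n_spurious, len(world.background)), replace=False)
            for p in sorted(picks):
                cls = int(rng.integers(1, world.spec.n_classes))
                term.add((world.background[p],), {cls})
        if spec.bg_coverage:
            n_bg = round(spec.bg_coverage * len(world.background))
            picks = rng.choice(len(world.background), size=n_bg, replace=False)
            for p in sorted(picks):
                w = (world.background[p],)
                if w not in term.entries:  # spurious assignments take precedence
                    term.add(w, {0})
        out.append(term)
    return out


def calibrated_precision_source(
    world: World,
    corpus: list[Document],
    target_precision: float,
    recall: float = 1.0,
    seed: int = 0,
    name: str = "noisy_src",
) -> Terminology:
    """Build a high-recall source whose word-level precision on ``corpus``
    approximates ``target_precision`` by adding spurious background terms
    until the expected false-positive token mass reaches the target ratio.

    Precision is a corpus-dependent quantity, so the spurious set is sized
    from observed token frequencies rather than fixed a priori.
    """
    rng = np.random.default_rng(seed)
    all_terms = sorted(world.all_terms().items())
    n_known = max(1, round(recall * len(all_terms)))
    known = [all_terms[i] for i in sorted(rng.choice(len(all_terms), size=n_known, replace=False))]
    known_set = {t for t, _ in known}

    counts: dict[str, int] = {}
    tp_tokens = 0
    for doc in corpus:
        for sent in doc.sentences:
            for tok in sent.tokens:
                counts[tok] = counts.get(tok, 0) + 1
    entity_tokens = {tok for t in known_set for tok in t}
    tp_tokens = sum(counts.get(tok, 0) for tok in entity_tokens)

    term = Terminology(name)
    for t, cls in known:
        term.add(t, {cls})
    if target_precision >= 1.0 or tp_tokens == 0:
        return term
    fp_needed = tp_tokens * (1.0 - target_precision) / target_precision
    order = rng.permutation(len(world.background))
    fp = 0.0
    for j in order:
        if fp >= fp_needed:
            break
        w = world.background[j]
        c = counts.get(w, 0)
        if c == 0:
            continue
        term.add((w,), {int(rng.integers(1, world.spec.n_classes))})
        fp += c
    return term


# ---------------------------------------------------------------------------
# Direct label-matrix generation (exercises the label model alone)
# ---------------------------------------------------------------------------


def generate_label_matrix(
    n: int,
    accuracies: list[float],
    abstain_rates: list[float],
    class_balance: list[float],
    seed: int = 0,
) -> tuple[LabelMatrix, np.ndarray]:
    """Draw true labels from ``class_balance``; each LF abstains
    independently at its rate, otherwise votes the truth with probability
    equal to its accuracy and a uniformly random wrong class otherwise."""
    if len(accuracies) != len(abstain_rates):
        raise ValueError("accuracies and abstain_rates must have equal length")
    if not all(0.0 < a < 1.0 for a in accuracies):
        raise ValueError("accuracies must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    K = len(class_balance)
    m = len(accuracies)
    y = rng.choice(K, size=n, p=np.asarray(class_balance) / np.sum(class_balance))
    L = np.empty((n, m), dtype=np.int64)
    for i, (acc, ab) in enumerate(zip(accuracies, abstain_rates)):
        correct = rng.random(n) < acc
        shift = rng.integers(1, K, size=n)  # uniform over the K-1 wrong classes
        votes = np.where(correct, y, (y + shift) % K)
        votes[rng.random(n) < ab] = -1
        L[:, i] = votes
    row_index = [("synthetic", 0, t) for t in range(n)]
    return LabelMatrix(L, row_index, [f"lf{i}" for i in range(m)]), y


# ---------------------------------------------------------------------------
# Worked-example fixture: partial-coverage sources truncate a multi-token span
# ---------------------------------------------------------------------------


def span_disagreement_fixture() -> tuple[list[Document], list[Terminology], dict[str, list[Span]], int]:
    """A sentence containing the entity "diabetes type 2" labeled by four
    sources: two know the full three-token term, two know only "diabetes".

    With unmatched tokens labeled as the negative class, majority vote ties
    2-2 on "type" and "2" and truncates the span to "diabetes" alone; a
    label model whose accuracies favor the full-term sources recovers the
    complete span.
    """
    doc = doc_from_sentences("example_doc", [["the", "patient", "has", "diabetes", "type", "2", "today"]])
    full = ("diabetes", "type", "2")
    partial = ("diabetes",)
    terms = []
    for name in ("source_full_a", "source_full_b"):
        t = Terminology(name)
        t.add(full, {1})
        t.add(partial, {1})
        terms.append(t)
    for name in ("source_partial_a", "source_partial_b"):
        t = Terminology(name)
        t.add(partial, {1})
        terms.append(t)
    gold = {"example_doc": [Span("example_doc", 0, 3, 6, 1)]}
    return [doc], terms, gold, 2
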