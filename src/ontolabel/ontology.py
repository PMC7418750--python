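"""Terminology ingestion and organization into label sources.

A terminology is a flat set of normalized terms with class assignments
(semantic types mapped to target classes). Terminologies become labeling
functions downstream; this module handles normalization, semantic-type
distributions, coverage ranking, and partitioning into individual vs. merged
sources.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from ._stopwords import STOPWORDS
from .corpus import Document

logger = logging.getLogger(__name__)

REJECT = None

_NUMBER_RE = re.compile(r"[0-9][0-9.,%/-]*")


@dataclass(frozen=True)
class NormConfig:
    """Term normalization knobs.

    Abbreviation heuristic: a token keeps its case iff it has at most
    ``abbrev_max_len`` characters and either contains >= 2 uppercase letters
    or is entirely uppercase; all other tokens are lowercased. Matching then
    compares abbreviation-like tokens case-sensitively and everything else
    case-insensitively.
    """

    abbrev_max_len: int = 6
    stopwords: frozenset[str] = STOPWORDS
    min_chars: int = 2  # single-character terms are dropped


DEFAULT_NORM = NormConfig()


def match_key(token: str, config: NormConfig = DEFAULT_NORM) -> str:
    """Case-normalize one token, preserving abbreviation-like tokens.

    Shared by the term store and the sequence matcher so both sides agree.
    """
    if len(token) <= config.abbrev_max_len:
        n_upper = sum(c.isupper() for c in token)
        has_alpha = any(c.isalpha() for c in token)
        if n_upper >= 2 or (has_alpha and token == token.upper()):
            return token
    return token.lower()


def normalize_term(raw: str, config: NormConfig = DEFAULT_NORM):
    """Normalize a raw term string to a token tuple, or REJECT (None).

    Rejected: stopwords, pure numbers, and terms under ``min_chars``
    characters (after trimming). Multi-word terms are rejected only when
    every token would individually be rejected.
    """
    if not raw or not raw.strip():
        raise ValueError("term must be non-empty")
    tokens = raw.split()

    def rejected(tok: str) -> bool:
        return (
            len(tok) < config.min_chars
            or tok.lower() in config.stopwords
            or _NUMBER_RE.fullmatch(tok) is not None
        )

    if all(rejected(t) for t in tokens):
        return REJECT
    return tuple(match_key(t, config) for t in tokens)


@dataclass
class Terminology:
    """One label source: normalized terms mapped to sets of target classes."""

    name: str
    entries: dict[tuple[str, ...], set[int]] = field(default_factory=dict)

    def add(self, term: tuple[str, ...], classes: set[int]) -> None:
        if not term:
            raise ValueError("empty term")
        self.entries.setdefault(term, set()).update(classes)

    def terms(self) -> set[tuple[str, ...]]:
        return set(self.entries)

    @property
    def max_term_len(self) -> int:
        return max((len(t) for t in self.entries), default=0)

    def merged_with(self, other: "Terminology", name: str | None = None) -> "Terminology":
        out = Terminology(name or f"{self.name}+{other.name}")
        for src in (self, other):
            for term, classes in src.entries.items():
                out.add(term, set(classes))
        return out

    def __len__(self) -> int:
        return len(self.entries)


def load_terminology(path, class_map: dict[str, int], name: str | None = None,
                     config: NormConfig = DEFAULT_NORM) -> Terminology:
    """Load one terminology from TSV (term<TAB>source<TAB>semantic_type) or
    JSON ({"name", "entries": [{"term", "types"}]}).

    Semantic types are mapped through ``class_map`` (type id -> class id;
    -1 means ignore); unmapped types are dropped, and entries left with no
    mapped type are dropped. Rejected terms are counted and logged.
    """
    path = str(path)
    rows: list[tuple[str, str, list[str]]] = []
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        src = data.get("name", name or "terminology")
        for ent in data.get("entries", []):
            rows.append((ent["term"], src, list(ent.get("types", []))))
    else:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            required = ["term", "source", "semantic_type"]
            if header[: len(required)] != required:
                raise ValueError(f"{path}:1: expected columns {required}, got {header}")
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
                rows.append((parts[0], parts[1], [parts[2]]))

    sources = {src for _, src, _ in rows}
    if name is None:
        name = sources.pop() if len(sources) == 1 else "terminology"
    term = Terminology(name)
    n_rejected = 0
    for raw, _, types in rows:
        norm = normalize_term(raw, config)
        if norm is REJECT:
            n_rejected += 1
            continue
        classes = {class_map[t] for t in types if t in class_map and class_map[t] >= 0}
        if not classes:
            continue
        term.add(norm, classes)
    if n_rejected:
        logger.info("%s: rejected %d terms during normalization", name, n_rejected)
    if not term.entries:
        logger.warning("%s: terminology is empty after normalization/mapping", name)
    return term


def save_terminology_tsv(term: Terminology, path) -> None:
    """Write the TSV interchange format (term, source, semantic_type); class
    ids serve as type ids and round-trip through an identity class map."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tsource\tsemantic_type\n")
        for t in sorted(term.entries):
            for c in sorted(term.entries[t]):
                fh.write(f"{' '.join(t)}\t{term.name}\t{c}\n")


@dataclass
class SemanticTypeMap:
    """Per-term probability vector over the K classes (class 0 = negative),
    built from provenance counts of (terminology, term, class) assignments."""

    n_classes: int
    counts: dict[tuple[str, ...], np.ndarray] = field(default_factory=dict)

    def vector(self, term: tuple[str, ...]) -> np.ndarray | None:
        c = self.counts.get(term)
        if c is None:
            return None
        return c / c.sum()

    def most_probable(self, term: tuple[str, ...]) -> tuple[int | None, bool]:
        """(argmax class, tie flag). Ties must make the caller abstain."""
        c = self.counts.get(term)
        if c is None:
            return None, False
        top = np.flatnonzero(c == c.max())
        return int(top[0]), len(top) > 1

    def __contains__(self, term) -> bool:
        return term in self.counts


def build_type_distribution(terminologies: list[Terminology], n_classes: int) -> SemanticTypeMap:
    """Count each (terminology, term, class) assignment once and normalize
    per term into a class probability vector."""
    if not terminologies:
        raise ValueError("need at least one terminology")
    out = SemanticTypeMap(n_classes)
    for term in terminologies:
        for t, classes in term.entries.items():
            vec = out.counts.setdefault(t, np.zeros(n_classes))
            for c in classes:
                if 0 <= c < n_classes:
                    vec[c] += 1
    return out


# ---------------------------------------------------------------------------
# Coverage ranking and partitioning
# ---------------------------------------------------------------------------


def _longest_matches(keys: list[str], terms: set[tuple[str, ...]], max_len: int):
    """Greedy leftmost-longest matching over normalized token keys.

    Yields (start, end, term) for non-overlapping maximal matches.
    """
    n = len(keys)
    i = 0
    while i < n:
        hit = None
        for L in range(min(max_len, n - i), 0, -1):
            cand = tuple(keys[i : i + L])
            if cand in terms:
                hit = (i, i + L, cand)
                break
        if hit is not None:
            yield hit
            i = hit[1]
        else:
            i += 1


def doc_match_keys(doc: Document, config: NormConfig = DEFAULT_NORM) -> list[list[str]]:
    return [[match_key(t, config) for t in sent.tokens] for sent in doc.sentences]


def rank_by_coverage(
    terminologies: list[Terminology],
    corpus: list[Document],
    config: NormConfig = DEFAULT_NORM,
) -> list[Terminology]:
    """Rank terminologies by coverage on an unlabeled corpus.

    score(v) = sum over terms t in v of the number of documents containing
    t as a longest match; descending, ties broken by terminology name.
    Invariant to document order.
    """
    keyed = [doc_match_keys(doc, config) for doc in corpus]
    scores: dict[str, int] = {}
    for term in terminologies:
        terms = term.terms()
        score = 0
        for doc_keys in keyed:
            seen: set[tuple[str, ...]] = set()
            for keys in doc_keys:
                for _, _, t in _longest_matches(keys, terms, term.max_term_len):
                    seen.add(t)
            score += len(seen)
        scores[term.name] = score
    return sorted(terminologies, key=lambda v: (-scores[v.name], v.name))


@dataclass
class SourcePartition:
    """Top-s terminologies kept individual; the rest merged into one union
    source."""

    individual_sources: list[Terminology]
    merged_remainder: Terminology | None
    s: int

    def label_sources(self) -> list[Terminology]:
        out = list(self.individual_sources)
        if self.merged_remainder is not None and len(self.merged_remainder):
            out.append(self.merged_remainder)
        return out


def partition_sources(ranked: list[Terminology], s: int) -> SourcePartition:
    """Keep the top-s terminologies as individual label sources and merge
    the remainder into a single union terminology."""
    if not 1 <= s <= len(ranked):
        raise ValueError(f"s={s} out of range [1, {len(ranked)}]")
    individual = list(ranked[:s])
    rest = ranked[s:]
    merged: Terminology | None = None
    if rest:
        merged = Terminology("merged_remainder")
        for t in rest:
            for term, classes in t.entries.items():
                merged.add(term, set(classes))
    return SourcePartition(individual, merged, s)
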