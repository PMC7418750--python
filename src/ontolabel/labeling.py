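"""Labeling-function templates and label-matrix construction.

Four LF kinds are implemented:

* semantic_type — greedy longest-match dictionary tagging against one
  terminology, assigning each match its most probable class from a
  semantic-type distribution (abstain on exact ties), with optional
  slot-filled patterns for simple compositional mentions like
  "Tylenol (Acetaminophen)".
* synset — document-scoped synonym sets: a synset fires only when >= 2
  distinct member terms match somewhere in the document, then labels all
  member occurrences; optional Schwartz-Hearst linking of out-of-dictionary
  abbreviations defined as "long form (SF)".
* context_window — cue rules for span tasks (negation, document-relative
  time): scan left/right token windows around a pre-identified entity for
  trigger phrases, plus a nearest-datetime heuristic against the document
  timestamp.
* pattern — regex or small-dictionary rules emitting a fixed class
  (including the negative class 0, e.g. punctuation guidelines).

Votes are integers in {-1, 0, ..., K-1}; -1 abstains.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import ABSTAIN, Document, Span, TokenSequence
from .ontology import (
    DEFAULT_NORM,
    NormConfig,
    SemanticTypeMap,
    Terminology,
    _longest_matches,
    match_key,
)

logger = logging.getLogger(__name__)


def sequence_keys(seq: TokenSequence, config: NormConfig = DEFAULT_NORM) -> list[str]:
    return [match_key(t, config) for t in seq.tokens]


# ---------------------------------------------------------------------------
# Base classes
# ---------------------------------------------------------------------------


class LabelingFunction:
    """Token-level LF: labels every token of every sentence of a document."""

    name: str
    kind: str

    def label_sequence(self, seq: TokenSequence) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def label_document(self, doc: Document) -> list[np.ndarray]:
        out = []
        for sent in doc.sentences:
            vec = self.label_sequence(sent)
            if len(vec) != len(sent):
                raise AssertionError(f"{self.name}: label vector length mismatch")
            out.append(vec)
        return out


class SpanLabelingFunction:
    """Span-level LF: labels pre-identified entity spans (span tasks)."""

    name: str
    kind = "context_window"

    def label_spans(self, doc: Document, spans: list[Span]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Semantic-type LF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Candidate:
    start: int
    end: int
    label: int  # ABSTAIN encodes an argmax tie
    is_pattern: bool
    prob: float

    @property
    def length(self) -> int:
        return self.end - self.start


class SemanticTypeLF(LabelingFunction):
    """Longest-match dictionary LF over one terminology.

    Matched tokens get the argmax class of the term's type distribution
    (abstaining on exact ties); unmatched tokens get -1 (``unmatched="abstain"``)
    or the negative class 0 (``unmatched="negative"``). Slot-filled
    ``{*} ({*})`` patterns fire when both slots independently match terms of
    the same class, labeling the whole region including the parentheses;
    patterns beat plain matches of equal length, but longer plain matches
    beat nested patterns.
    """

    kind = "semantic_type"

    def __init__(
        self,
        name: str,
        terminology: Terminology,
        type_map: SemanticTypeMap,
        unmatched: str = "abstain",
        slot_patterns: bool = True,
        config: NormConfig = DEFAULT_NORM,
    ):
        if unmatched not in ("abstain", "negative"):
            raise ValueError("unmatched must be 'abstain' or 'negative'")
        self.name = name
        self.terminology = terminology
        self.type_map = type_map
        self.unmatched_value = ABSTAIN if unmatched == "abstain" else 0
        self.slot_patterns = slot_patterns
        self.config = config

    def _term_label(self, term: tuple[str, ...]) -> tuple[int, float]:
        cls, tie = self.type_map.most_probable(term)
        if cls is None or tie:
            vec = self.type_map.vector(term)
            return ABSTAIN, 0.0 if vec is None else float(vec.max())
        return cls, float(self.type_map.vector(term)[cls])

    def _plain_candidates(self, keys: list[str]) -> list[_Candidate]:
        terms = self.terminology.terms()
        out = []
        for s, e, term in _longest_matches(keys, terms, self.terminology.max_term_len):
            cls, prob = self._term_label(term)
            out.append(_Candidate(s, e, cls, False, prob))
        return out

    def _pattern_candidates(self, keys: list[str]) -> list[_Candidate]:
        """The attested slot pattern: ``{*} ({*})``."""
        terms = self.terminology.terms()
        max_len = self.terminology.max_term_len
        out = []
        n = len(keys)
        for j, tok in enumerate(keys):
            if tok != "(":
                continue
            try:
                l = keys.index(")", j + 1)
            except ValueError:
                continue
            inner = tuple(keys[j + 1 : l])
            if not inner or inner not in terms:
                continue
            left = None
            for L in range(min(max_len, j), 0, -1):
                cand = tuple(keys[j - L : j])
                if cand in terms:
                    left = (j - L, cand)
                    break
            if left is None:
                continue
            lcls, ltie = self.type_map.most_probable(left[1])
            rcls, rtie = self.type_map.most_probable(inner)
            if lcls is None or rcls is None or ltie or rtie or lcls != rcls:
                continue
            out.append(_Candidate(left[0], l + 1, lcls, True, 1.0))
        return out

    def label_sequence(self, seq: TokenSequence) -> np.ndarray:
        keys = sequence_keys(seq, self.config)
        cands = self._plain_candidates(keys)
        if self.slot_patterns:
            cands += self._pattern_candidates(keys)
        # longest first; patterns beat equal-length plain matches; higher
        # class probability breaks remaining ties, then leftmost.
        cands.sort(key=lambda c: (-c.length, c.is_pattern is False, -c.prob, c.start))
        vec = np.full(len(seq), self.unmatched_value, dtype=np.int64)
        taken = np.zeros(len(seq), dtype=bool)
        for c in cands:
            if taken[c.start : c.end].any():
                continue
            vec[c.start : c.end] = c.label
            taken[c.start : c.end] = True
        return vec


# ---------------------------------------------------------------------------
# Synset LF (+ Schwartz-Hearst abbreviation linking)
# ---------------------------------------------------------------------------


@dataclass
class Synset:
    """A set of >= 2 synonymous normalized terms sharing one concept."""

    concept_id: str
    terms: set[tuple[str, ...]]
    label: int

    def __post_init__(self) -> None:
        if len(self.terms) < 2:
            raise ValueError(f"synset {self.concept_id} needs >= 2 terms")


def _sh_valid_short_form(sf: str) -> bool:
    return 2 <= len(sf) <= 10 and any(c.isalpha() for c in sf) and sf[0].isalnum()


def _sh_best_long_form(sf: str, candidate: list[str]) -> list[str] | None:
    """Schwartz-Hearst character matching: find the shortest token suffix of
    ``candidate`` whose characters contain the short form's characters in
    order, with the first short-form character starting a long-form token."""
    text_tokens = candidate
    for start in range(len(text_tokens) - 1, -1, -1):
        lf = " ".join(text_tokens[start:])
        i, j = len(sf) - 1, len(lf) - 1
        while i >= 0:
            c = sf[i].lower()
            if not c.isalnum():
                i -= 1
                continue
            while j >= 0 and lf[j].lower() != c:
                j -= 1
            if j < 0:
                break
            # first character of sf must begin a long-form token
            if i == 0 and not (j == 0 or lf[j - 1] == " "):
                j -= 1
                continue
            i -= 1
            j -= 1
        if i < 0:
            return text_tokens[start:]
    return None


def schwartz_hearst_pairs(doc: Document, config: NormConfig = DEFAULT_NORM) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Extract (long form, short form) abbreviation definitions of the shape
    ``long form (SF)`` from a document, as normalized token tuples."""
    pairs = []
    for sent in doc.sentences:
        toks = sent.tokens
        for j, tok in enumerate(toks):
            if tok != "(" or j + 2 >= len(toks) + 1:
                continue
            try:
                l = toks.index(")", j + 1)
            except ValueError:
                continue
            if l - j != 2:  # single-token short forms only
                continue
            sf = toks[j + 1]
            if not _sh_valid_short_form(sf):
                continue
            n_words = min(len(sf) + 5, len(sf) * 2)
            cand = toks[max(0, j - n_words) : j]
            long_form = _sh_best_long_form(sf, cand)
            if long_form:
                pairs.append(
                    (
                        tuple(match_key(t, config) for t in long_form),
                        (match_key(sf, config),),
                    )
                )
    return pairs


class SynsetLF(LabelingFunction):
    """Document-scoped synonym LF.

    A synset fires iff >= 2 distinct member terms each match somewhere in
    the parent document; all occurrences of any member are then labeled the
    synset's class. With ``schwartz_hearst=True``, short forms defined in the
    document as "long form (SF)" are linked as temporary members when the
    long form belongs to the synset.
    """

    kind = "synset"

    def __init__(
        self,
        name: str,
        synsets: list[Synset],
        unmatched: str = "abstain",
        schwartz_hearst: bool = False,
        config: NormConfig = DEFAULT_NORM,
    ):
        self.name = name
        self.synsets = sorted(synsets, key=lambda s: s.concept_id)
        self.unmatched_value = ABSTAIN if unmatched == "abstain" else 0
        self.schwartz_hearst = schwartz_hearst
        self.config = config

    def label_sequence(self, seq: TokenSequence) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError("synset LFs are document-scoped; use label_document")

    def label_document(self, doc: Document) -> list[np.ndarray]:
        keyed = [sequence_keys(s, self.config) for s in doc.sentences]
        vecs = [np.full(len(s), self.unmatched_value, dtype=np.int64) for s in doc.sentences]
        sh_pairs = schwartz_hearst_pairs(doc, self.config) if self.schwartz_hearst else []
        for synset in self.synsets:
            members = set(synset.terms)
            for long_form, short_form in sh_pairs:
                if long_form in members:
                    members.add(short_form)
            max_len = max(len(t) for t in members)
            hits: list[tuple[int, int, int]] = []
            matched_terms: set[tuple[str, ...]] = set()
            for si, keys in enumerate(keyed):
                for s, e, term in _longest_matches(keys, members, max_len):
                    hits.append((si, s, e))
                    matched_terms.add(term)
            if len(matched_terms) < 2:
                continue
            for si, s, e in hits:
                seg = vecs[si][s:e]
                unset = seg == self.unmatched_value
                seg[unset] = synset.label
        return vecs


# ---------------------------------------------------------------------------
# Context-window cue LF (span tasks)
# ---------------------------------------------------------------------------


@dataclass
class CuePattern:
    """A trigger searched in a token window around an entity span."""

    direction: str  # left | right | either
    window: int
    trigger: str  # literal phrase, or regex if ``regex=True``
    label: int
    regex: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right", "either"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.regex:
            try:
                self._rx = re.compile(self.trigger, re.IGNORECASE)
            except re.error as err:  # configuration error at load time
                raise ValueError(f"invalid regex {self.trigger!r}: {err}") from err
        else:
            self._phrase = tuple(self.trigger.lower().split())

    def matches(self, window_tokens: list[str]) -> bool:
        if self.regex:
            return self._rx.search(" ".join(window_tokens)) is not None
        low = [t.lower() for t in window_tokens]
        k = len(self._phrase)
        return any(tuple(low[i : i + k]) == self._phrase for i in range(len(low) - k + 1))


_MONTHS = {
    m.lower(): i + 1
    for i, m in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"]
    )
}
_ISO_RE = re.compile(r"(\d{4})-(\d{2})-(\d{2})")
_MDY_RE = re.compile(r"(\d{1,2})/(\d{1,2})/(\d{4})")


def parse_date_at(tokens: list[str], i: int) -> datetime.date | None:
    """Parse a datetime mention starting at token i: ISO (YYYY-MM-DD),
    MM/DD/YYYY, or "Month D, YYYY" (also "Month D YYYY")."""
    tok = tokens[i]
    m = _ISO_RE.fullmatch(tok) or _MDY_RE.fullmatch(tok)
    try:
        if m and _ISO_RE.fullmatch(tok):
            return datetime.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        if m:
            return datetime.date(int(m.group(3)), int(m.group(1)), int(m.group(2)))
        if tok.lower() in _MONTHS and i + 1 < len(tokens):
            day_tok = tokens[i + 1].rstrip(",")
            if not day_tok.isdigit():
                return None
            j = i + 2
            if j < len(tokens) and tokens[j] == ",":
                j += 1
            if j < len(tokens) and tokens[j].isdigit() and len(tokens[j]) == 4:
                return datetime.date(int(tokens[j]), _MONTHS[tok.lower()], int(day_tok))
    except ValueError:
        return None
    return None


class ContextWindowLF(SpanLabelingFunction):
    """Cue-phrase LF for span tasks: scan a token window in the configured
    direction(s) around each entity span for triggers; first hit wins.

    With ``datetime_labels`` configured, a nearest-datetime heuristic fires
    when no cue does: the explicit datetime mention nearest to the span (in
    token distance, within the window) is compared to the document timestamp
    and the before/after/overlap class is emitted. Missing document
    timestamps make the rule abstain (logged once per document).
    """

    def __init__(
        self,
        name: str,
        cues: list[CuePattern] = (),
        datetime_labels: dict[str, int] | None = None,
        datetime_window: int = 30,
    ):
        self.name = name
        self.cues = list(cues)
        self.datetime_labels = datetime_labels
        self.datetime_window = datetime_window

    def _windows(self, seq: TokenSequence, span: Span, window: int) -> dict[str, list[str]]:
        left = seq.tokens[max(0, span.token_start - window) : span.token_start]
        right = seq.tokens[span.token_end : span.token_end + window]
        return {"left": left, "right": right, "either": left + right}

    def _datetime_vote(self, doc: Document, seq: TokenSequence, span: Span) -> int:
        if doc.timestamp is None:
            if not getattr(doc, "_dt_warned", False):
                logger.warning("doc %s has no timestamp; datetime rule abstains", doc.doc_id)
                doc._dt_warned = True  # type: ignore[attr-defined]
            return ABSTAIN
        best: tuple[int, datetime.date] | None = None
        for i in range(len(seq)):
            d = parse_date_at(seq.tokens, i)
            if d is None:
                continue
            if i >= span.token_end:
                dist = i - span.token_end + 1
            elif i < span.token_start:
                dist = span.token_start - i
            else:
                dist = 0
            if dist <= self.datetime_window and (best is None or dist < best[0]):
                best = (dist, d)
        if best is None:
            return ABSTAIN
        d = best[1]
        if d < doc.timestamp:
            return self.datetime_labels.get("before", ABSTAIN)
        if d > doc.timestamp:
            return self.datetime_labels.get("after", ABSTAIN)
        return self.datetime_labels.get("overlap", ABSTAIN)

    def label_spans(self, doc: Document, spans: list[Span]) -> np.ndarray:
        by_sent = {s.sent_index: s for s in doc.sentences}
        out = np.full(len(spans), ABSTAIN, dtype=np.int64)
        for k, span in enumerate(spans):
            seq = by_sent[span.sent_index]
            vote = ABSTAIN
            for cue in self.cues:
                win = self._windows(seq, span, cue.window)[cue.direction]
                if cue.matches(win):
                    vote = cue.label
                    break
            if vote == ABSTAIN and self.datetime_labels is not None:
                vote = self._datetime_vote(doc, seq, span)
            out[k] = vote
        return out


# ---------------------------------------------------------------------------
# Pattern LF
# ---------------------------------------------------------------------------


class PatternLF(LabelingFunction):
    """Regex or small-dictionary rule emitting one class (possibly the
    negative class 0). Unmatched tokens abstain unless ``unmatched="negative"``."""

    kind = "pattern"

    def __init__(
        self,
        name: str,
        label: int,
        regex: str | None = None,
        dictionary: set[tuple[str, ...]] | None = None,
        unmatched: str = "abstain",
        config: NormConfig = DEFAULT_NORM,
    ):
        if (regex is None) == (dictionary is None):
            raise ValueError("exactly one of regex/dictionary required")
        self.name = name
        self.label = label
        self.unmatched_value = ABSTAIN if unmatched == "abstain" else 0
        self.config = config
        self.dictionary = dictionary
        if regex is not None:
            try:
                self.rx = re.compile(regex)
            except re.error as err:
                raise ValueError(f"{name}: invalid regex {regex!r}: {err}") from err
        else:
            self.rx = None
            self._max_len = max((len(t) for t in dictionary), default=0)

    def label_sequence(self, seq: TokenSequence) -> np.ndarray:
        vec = np.full(len(seq), self.unmatched_value, dtype=np.int64)
        if self.rx is not None:
            # match against the space-joined sentence; tokens overlapping a
            # regex match get the class
            text = " ".join(seq.tokens)
            starts, pos = [], 0
            for t in seq.tokens:
                starts.append(pos)
                pos += len(t) + 1
            for m in self.rx.finditer(text):
                for i, t in enumerate(seq.tokens):
                    if starts[i] < m.end() and starts[i] + len(t) > m.start():
                        vec[i] = self.label
        else:
            keys = sequence_keys(seq, self.config)
            for s, e, _ in _longest_matches(keys, self.dictionary, self._max_len):
                vec[s:e] = self.label
        return vec


# ---------------------------------------------------------------------------
# Label matrix
# ---------------------------------------------------------------------------


@dataclass
class LabelMatrix:
    """Votes of m LFs over n units (corpus tokens, or spans for span tasks).

    ``values`` is (n, m) int in {-1, 0, ..., K-1}; ``row_index`` maps rows to
    (doc_id, sent_index, token_index) (or span tuples); ``lf_names`` maps
    columns to LF names.
    """

    values: np.ndarray
    row_index: list[tuple]
    lf_names: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.row_index):
            raise ValueError("row_index length mismatch")
        if self.values.shape[1] != len(self.lf_names):
            raise ValueError("lf_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def save(self, prefix) -> None:
        """Write <prefix>.npz (values) and <prefix>.rows.tsv (row index +
        LF names header)."""
        np.savez_compressed(f"{prefix}.npz", values=self.values)
        with open(f"{prefix}.rows.tsv", "w", encoding="utf-8") as fh:
            fh.write("#lfs\t" + "\t".join(self.lf_names) + "\n")
            for row in self.row_index:
                fh.write("\t".join(str(x) for x in row) + "\n")

    @classmethod
    def load(cls, prefix) -> "LabelMatrix":
        values = np.load(f"{prefix}.npz")["values"]
        with open(f"{prefix}.rows.tsv", encoding="utf-8") as fh:
            lf_names = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                doc_id, sent, tok = line.rstrip("\n").split("\t")
                rows.append((doc_id, int(sent), int(tok)))
        return cls(values, rows, lf_names)

    def to_tsv(self, path) -> None:
        """Human-readable debug dump."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("doc_id\tsent\ttok\t" + "\t".join(self.lf_names) + "\n")
            for row, votes in zip(self.row_index, self.values):
                fh.write("\t".join(str(x) for x in row) + "\t" + "\t".join(map(str, votes)) + "\n")


def build_label_matrix(lfs: list[LabelingFunction], corpus: list[Document]) -> LabelMatrix:
    """Apply every token-level LF to every token, in corpus order."""
    names = [lf.name for lf in lfs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate LF names: {names}")
    if not lfs:
        raise ValueError("need at least one LF")
    row_index = [
        (doc.doc_id, sent.sent_index, t)
        for doc in corpus
        for sent in doc.sentences
        for t in range(len(sent))
    ]
    cols = []
    for lf in lfs:
        col = np.concatenate([v for doc in corpus for v in lf.label_document(doc)]) if row_index else np.zeros(0, dtype=np.int64)
        cols.append(col)
    values = np.stack(cols, axis=1) if cols else np.zeros((0, 0), dtype=np.int64)
    return LabelMatrix(values, row_index, names)


def build_span_label_matrix(
    lfs: list[SpanLabelingFunction], corpus: list[Document], spans_by_doc: dict[str, list[Span]]
) -> LabelMatrix:
    """Apply span-level LFs to pre-identified entity spans (span tasks)."""
    names = [lf.name for lf in lfs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate LF names: {names}")
    row_index = [
        (doc.doc_id, sp.sent_index, sp.token_start, sp.token_end)
        for doc in corpus
        for sp in spans_by_doc.get(doc.doc_id, [])
    ]
    cols = []
    for lf in lfs:
        parts = [lf.label_spans(doc, spans_by_doc.get(doc.doc_id, [])) for doc in corpus]
        cols.append(np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64))
    values = np.stack(cols, axis=1)
    return LabelMatrix(values, row_index, names)
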