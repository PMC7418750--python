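"""Core text data model: documents, token sequences, spans, and tag schemes.

All coordinates are 0-based, half-open — both character offsets within a
document and token indices within a sentence. Entity classes are integers;
class 0 is the negative ("outside") class, classes 1..K-1 are entity types,
and -1 denotes an abstaining vote (used only in label matrices, never in
tags).
"""

from __future__ import annotations

import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

ABSTAIN = -1
OUTSIDE = 0

IO = "IO"
BIO = "BIO"


# ---------------------------------------------------------------------------
# Tokenization (pluggable; default is a deterministic rule-based splitter)
# ---------------------------------------------------------------------------

_PUNCT = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")
_ACRONYM_RE = re.compile(r"(?:[A-Za-z]\.){2,}")


def simple_tokenize(text: str) -> list[tuple[str, int, int]]:
    """Whitespace split, then peel leading/trailing punctuation into their
    own tokens.

    Internal hyphens and periods inside acronyms ("U.S.") are preserved.
    Returns (token, start, end) triples with offsets into ``text``.
    """
    out: list[tuple[str, int, int]] = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(0), m.start()
        # leading punctuation
        lead = 0
        while lead < len(chunk) - 1 and chunk[lead] in _PUNCT:
            out.append((chunk[lead], start + lead, start + lead + 1))
            lead += 1
        chunk, start = chunk[lead:], start + lead
        # trailing punctuation (keep the final period of acronyms)
        trail: list[tuple[str, int, int]] = []
        while len(chunk) > 1 and chunk[-1] in _PUNCT:
            if chunk[-1] == "." and _ACRONYM_RE.fullmatch(chunk):
                break
            trail.append((chunk[-1], start + len(chunk) - 1, start + len(chunk)))
            chunk = chunk[:-1]
        if chunk:
            out.append((chunk, start, start + len(chunk)))
        out.extend(reversed(trail))
    return out


_SENT_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character ranges of sentences: split on .?! followed by whitespace
    and an uppercase letter. Overridable by supplying pre-split input."""
    bounds = [0]
    for m in _SENT_BOUNDARY.finditer(text):
        bounds.append(m.end())
    bounds.append(len(text))
    return [(s, e) for s, e in zip(bounds, bounds[1:]) if text[s:e].strip()]


Tokenizer = Callable[[str], list[tuple[str, int, int]]]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class TokenSequence:
    """A sentence as ordered tokens with character offsets into the parent
    document's text."""

    tokens: list[str]
    offsets: list[tuple[int, int]]
    doc_ref: str = ""
    sent_index: int = 0

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.offsets):
            raise ValueError("tokens and offsets must have equal length")
        prev_end = -1
        for s, e in self.offsets:
            if not (prev_end <= s < e):
                raise ValueError(f"offsets must be strictly increasing and non-overlapping: {self.offsets}")
            prev_end = e

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[TokenSequence] = field(default_factory=list)
    timestamp: datetime.date | None = None

    def __post_init__(self) -> None:
        for sent in self.sentences:
            for tok, (s, e) in zip(sent.tokens, sent.offsets):
                if self.text and self.text[s:e] != tok:
                    raise ValueError(
                        f"token {tok!r} does not match text[{s}:{e}]={self.text[s:e]!r} in doc {self.doc_id}"
                    )

    def iter_tokens(self) -> Iterator[tuple[int, int, str]]:
        for sent in self.sentences:
            for t, tok in enumerate(sent.tokens):
                yield sent.sent_index, t, tok


@dataclass(frozen=True)
class Span:
    """A labeled entity span: token indices [token_start, token_end) within
    one sentence of one document."""

    doc_ref: str
    sent_index: int
    token_start: int
    token_end: int
    label: int

    def __post_init__(self) -> None:
        if not (0 <= self.token_start < self.token_end):
            raise ValueError(f"invalid span bounds [{self.token_start}, {self.token_end})")


@dataclass
class TagSequence:
    """Per-token tags under a named scheme (IO or BIO).

    Tags are "O" or "<prefix>-<class>" where prefix is I (or B in BIO) and
    class is the integer entity class.
    """

    tags: list[str]
    scheme: str = IO

    def __post_init__(self) -> None:
        if self.scheme not in (IO, BIO):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.tags)


def _tag(prefix: str, label: int) -> str:
    return f"{prefix}-{label}"


def _parse_tag(tag: str) -> tuple[str, int | None]:
    if tag == "O":
        return "O", None
    prefix, _, cls = tag.partition("-")
    return prefix, int(cls)


# ---------------------------------------------------------------------------
# Span <-> tag conversions
# ---------------------------------------------------------------------------


def spans_to_tags(spans: Sequence[Span], seq: TokenSequence, scheme: str = IO) -> TagSequence:
    """Project non-overlapping spans onto per-token tags.

    Raises on overlapping spans, naming the colliding pair.
    """
    n = len(seq)
    ordered = sorted(spans, key=lambda s: s.token_start)
    tags = ["O"] * n
    prev: Span | None = None
    for sp in ordered:
        if sp.token_end > n:
            raise ValueError(f"span {sp} exceeds sequence length {n}")
        if prev is not None and sp.token_start < prev.token_end:
            raise ValueError(f"overlapping spans: {prev} and {sp}")
        for t in range(sp.token_start, sp.token_end):
            if scheme == BIO and t == sp.token_start:
                tags[t] = _tag("B", sp.label)
            else:
                tags[t] = _tag("I", sp.label)
        prev = sp
    return TagSequence(tags, scheme)


def tags_to_spans(tag_seq: TagSequence, doc_ref: str = "", sent_index: int = 0) -> list[Span]:
    """Decode maximal contiguous tagged runs into spans.

    Malformed BIO (an I-x following O or a different class) is repaired by
    treating the I as B, with a logged warning.
    """
    spans: list[Span] = []
    start: int | None = None
    cur: int | None = None
    for t, tag in enumerate(tag_seq.tags):
        prefix, cls = _parse_tag(tag)
        if prefix == "O":
            if cur is not None:
                spans.append(Span(doc_ref, sent_index, start, t, cur))
            start = cur = None
        elif prefix == "B":
            if cur is not None:
                spans.append(Span(doc_ref, sent_index, start, t, cur))
            start, cur = t, cls
        else:  # I
            if tag_seq.scheme == BIO and (cur is None or cls != cur):
                logger.warning("malformed BIO at token %d (%s); treating I as B", t, tag)
                if cur is not None:
                    spans.append(Span(doc_ref, sent_index, start, t, cur))
                start, cur = t, cls
            elif tag_seq.scheme == IO and cur is not None and cls != cur:
                # class change inside an IO run starts a new span
                spans.append(Span(doc_ref, sent_index, start, t, cur))
                start, cur = t, cls
            elif cur is None:
                start, cur = t, cls
    if cur is not None:
        spans.append(Span(doc_ref, sent_index, start, len(tag_seq.tags), cur))
    return spans


def io_to_bio(tag_seq: TagSequence) -> TagSequence:
    """Rewrite I -> B at the start of each contiguous same-class run.

    Adjacent same-class IO runs are indistinguishable and merge into one BIO
    span — an inherent limitation of IO tagging.
    """
    if tag_seq.scheme != IO:
        raise ValueError("input must be IO-tagged")
    out: list[str] = []
    prev_cls: int | None = None
    for tag in tag_seq.tags:
        prefix, cls = _parse_tag(tag)
        if prefix == "O":
            out.append("O")
        elif cls != prev_cls:
            out.append(_tag("B", cls))
        else:
            out.append(_tag("I", cls))
        prev_cls = cls if prefix != "O" else None
    return TagSequence(out, BIO)


# ---------------------------------------------------------------------------
# Document construction and file I/O
# ---------------------------------------------------------------------------


def doc_from_text(
    doc_id: str,
    text: str,
    tokenizer: Tokenizer = simple_tokenize,
    timestamp: datetime.date | None = None,
    presplit: bool = False,
) -> Document:
    """Tokenize raw text into a Document (sentence split + tokenize)."""
    ranges = [(0, len(text))] if presplit else split_sentences(text)
    sentences = []
    for i, (s, e) in enumerate(ranges):
        triples = [(tok, s + a, s + b) for tok, a, b in tokenizer(text[s:e])]
        if not triples:
            continue
        sentences.append(
            TokenSequence(
                tokens=[t for t, _, _ in triples],
                offsets=[(a, b) for _, a, b in triples],
                doc_ref=doc_id,
                sent_index=len(sentences),
            )
        )
    return Document(doc_id, text, sentences, timestamp)


def doc_from_sentences(
    doc_id: str, sentences: list[list[str]], timestamp: datetime.date | None = None
) -> Document:
    """Build a Document from pre-tokenized sentences; text is synthesized by
    joining tokens with single spaces."""
    seqs: list[TokenSequence] = []
    parts: list[str] = []
    pos = 0
    for i, toks in enumerate(sentences):
        offsets = []
        for tok in toks:
            offsets.append((pos, pos + len(tok)))
            parts.append(tok)
            pos += len(tok) + 1
        seqs.append(TokenSequence(toks, offsets, doc_ref=doc_id, sent_index=i))
    return Document(doc_id, " ".join(parts), seqs, timestamp)


def read_jsonl_corpus(path, tokenizer: Tokenizer = simple_tokenize) -> list[Document]:
    """Read a JSONL corpus: one document per line, either
    {"doc_id", "text"} (raw) or {"doc_id", "sentences"} (pre-tokenized),
    with an optional ISO "timestamp"."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            rec = json.loads(line)
            ts = rec.get("timestamp")
            timestamp = datetime.date.fromisoformat(ts) if ts else None
            if "sentences" in rec:
                docs.append(doc_from_sentences(rec["doc_id"], rec["sentences"], timestamp))
            elif "text" in rec:
                docs.append(doc_from_text(rec["doc_id"], rec["text"], tokenizer, timestamp))
            else:
                raise ValueError(f"{path}:{lineno}: record needs 'text' or 'sentences'")
    return docs


def write_jsonl_corpus(path, docs: Iterable[Document]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec: dict = {"doc_id": doc.doc_id, "sentences": [s.tokens for s in doc.sentences]}
            if doc.timestamp is not None:
                rec["timestamp"] = doc.timestamp.isoformat()
            fh.write(json.dumps(rec) + "\n")


def write_conll(path, docs: Iterable[Document], tag_seqs: dict[tuple[str, int], TagSequence]) -> None:
    """Write token<TAB>tag lines, blank line between sentences."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            for sent in doc.sentences:
                tags = tag_seqs[(doc.doc_id, sent.sent_index)]
                for tok, tag in zip(sent.tokens, tags.tags):
                    fh.write(f"{tok}\t{tag}\n")
                fh.write("\n")


def read_conll(path, scheme: str = IO) -> list[tuple[list[str], TagSequence]]:
    """Read CoNLL-style token/tag pairs into (tokens, TagSequence) per
    sentence."""
    out: list[tuple[list[str], TagSequence]] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if toks:
                    out.append((toks, TagSequence(tags, scheme)))
                    toks, tags = [], []
                continue
            tok, _, tag = line.partition("\t")
            toks.append(tok)
            tags.append(tag)
    if toks:
        out.append((toks, TagSequence(tags, scheme)))
    return out
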