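"""Noise-aware discriminative sequence classifier.

Trains a per-token softmax classifier on the label model's probabilistic
labels, minimizing the expected cross-entropy under the soft labels
(noise-aware loss) with all-abstained tokens masked out of the loss. The
feature encoder is pluggable; the default hashes windowed lexical features
(token identity, shape, affix n-grams, +/-2 neighbors), a light-weight
stand-in for contextual embeddings that preserves the training semantics.
A hook accepts precomputed per-token embeddings instead.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .corpus import IO, Document, Span, TagSequence, TokenSequence
from .label_model import ProbLabels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------


def _shape(tok: str) -> str:
    out = []
    for ch in tok:
        c = "X" if ch.isupper() else "x" if ch.islower() else "d" if ch.isdigit() else ch
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


class HashedWindowEncoder:
    """Sparse indicator features per token, hashed into a fixed dimension.

    Features: token identity, lowercase form, character shape, 3-gram
    prefix/suffix, and lowercase neighbors at offsets +/-1, +/-2. Hashing is
    CRC32-based, stable across processes.
    """

    def __init__(self, dim: int = 2**15, window: int = 2):
        self.dim = dim
        self.window = window

    def _h(self, s: str) -> int:
        return zlib.crc32(s.encode("utf-8")) % self.dim

    def _token_features(self, tokens: list[str], i: int) -> list[int]:
        tok = tokens[i]
        low = tok.lower()
        feats = [f"w={tok}", f"lw={low}", f"shape={_shape(tok)}"]
        if len(low) >= 3:
            feats += [f"p3={low[:3]}", f"s3={low[-3:]}"]
        if len(low) >= 4:
            feats += [f"p4={low[:4]}", f"s4={low[-4:]}"]
        for d in range(1, self.window + 1):
            feats.append(f"lw[-{d}]=" + (tokens[i - d].lower() if i - d >= 0 else "<s>"))
            feats.append(f"lw[+{d}]=" + (tokens[i + d].lower() if i + d < len(tokens) else "</s>"))
        return [self._h(f) for f in feats]

    def encode(self, seq: TokenSequence) -> sp.csr_matrix:
        rows, cols = [], []
        for i in range(len(seq)):
            for j in self._token_features(seq.tokens, i):
                rows.append(i)
                cols.append(j)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(len(seq), self.dim))


class PrecomputedEncoder:
    """Embedding hook: serves externally computed per-token feature vectors,
    keyed by (doc_id, sent_index)."""

    def __init__(self, table: dict[tuple[str, int], np.ndarray], dim: int):
        self.table = table
        self.dim = dim

    def encode(self, seq: TokenSequence) -> sp.csr_matrix:
        X = self.table[(seq.doc_ref, seq.sent_index)]
        if X.shape != (len(seq), self.dim):
            raise ValueError(f"embedding shape {X.shape} != ({len(seq)}, {self.dim})")
        return sp.csr_matrix(X)


# ---------------------------------------------------------------------------
# Probabilistic training set
# ---------------------------------------------------------------------------


@dataclass
class ProbDataset:
    """Sequences paired with per-token soft labels, a train mask (False
    where every LF abstained), and train/valid split tags."""

    sequences: list[TokenSequence]
    soft_labels: list[np.ndarray]  # each (t, K)
    masks: list[np.ndarray]  # each (t,) bool
    splits: list[str]  # "train" | "valid"

    def __post_init__(self) -> None:
        for seq, y, m in zip(self.sequences, self.soft_labels, self.masks):
            if not (len(seq) == y.shape[0] == m.shape[0]):
                raise ValueError("sequence / soft-label / mask length mismatch")


def _doc_hash(seed: int, doc_id: str) -> int:
    digest = hashlib.md5(f"{seed}:{doc_id}".encode()).hexdigest()
    return int(digest[:8], 16)


def build_training_set(
    corpus: list[Document],
    problabels: ProbLabels,
    row_index: list[tuple],
    valid_frac: float = 0.1,
    seed: int = 0,
) -> ProbDataset:
    """Attach posteriors as soft labels; mask exactly the uncovered tokens;
    split train/valid deterministically by seeded document hash."""
    by_sent: dict[tuple[str, int], list[int]] = {}
    for r, (doc_id, sent, tok) in enumerate(row_index):
        by_sent.setdefault((doc_id, sent), []).append(r)
    seqs, ys, masks, splits = [], [], [], []
    for doc in corpus:
        split = "valid" if (_doc_hash(seed, doc.doc_id) % 1000) < valid_frac * 1000 else "train"
        for sent in doc.sentences:
            rows = by_sent.get((doc.doc_id, sent.sent_index))
            if rows is None or len(rows) != len(sent):
                got = 0 if rows is None else len(rows)
                raise ValueError(
                    f"alignment mismatch at ({doc.doc_id}, sent {sent.sent_index}): "
                    f"{len(sent)} tokens vs {got} label rows"
                )
            idx = np.array(rows)
            seqs.append(sent)
            ys.append(problabels.probs[idx])
            masks.append(problabels.covered[idx])
            splits.append(split)
    return ProbDataset(seqs, ys, masks, splits)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def noise_aware_loss(pred_dist: np.ndarray, soft_label: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Expected cross-entropy under the soft labels:
    -sum_y yhat(y) log pred(y), averaged over unmasked tokens.

    Reduces to the standard cross-entropy for one-hot soft labels, and by
    Gibbs' inequality is minimized at pred == soft label.
    """
    pred = np.atleast_2d(np.asarray(pred_dist, dtype=float))
    soft = np.atleast_2d(np.asarray(soft_label, dtype=float))
    if pred.shape != soft.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {soft.shape}")
    if (pred <= 0).any() and ((soft > 0) & (pred <= 0)).any():
        logger.warning("prediction has zero mass at a supported class; clipping at 1e-12")
    pred = np.clip(pred, 1e-12, None)
    per_token = -(soft * np.log(pred)).sum(axis=1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 0.0
        per_token = per_token[mask]
    return float(per_token.mean())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class EndModelConfig:
    lr: float = 0.5
    epochs: int = 30
    batch_size: int = 64
    l2: float = 1e-4
    warmup_frac: float = 0.1  # linear warmup, then linear decay
    patience: int = 5  # early-stopping patience on validation token F1
    seed: int = 0


@dataclass
class SequenceClassifier:
    W: np.ndarray  # (dim, K)
    b: np.ndarray  # (K,)
    encoder: object
    n_classes: int

    def predict_proba_matrix(self, X: sp.csr_matrix) -> np.ndarray:
        z = X @ self.W + self.b
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, seq: TokenSequence) -> np.ndarray:
        if len(seq) == 0:
            return np.zeros((0, self.n_classes))
        return self.predict_proba_matrix(self.encoder.encode(seq))


def _token_f1(pred: np.ndarray, gold: np.ndarray, n_classes: int) -> float:
    """Micro F1 over the positive classes (internal early-stopping score)."""
    pos_pred = pred != 0
    pos_gold = gold != 0
    tp = float(((pred == gold) & pos_gold).sum())
    fp = float((pos_pred & (pred != gold)).sum())
    fn = float((pos_gold & (pred != gold)).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _lr_at(step: int, total: int, base: float, warmup_frac: float) -> float:
    warm = max(1, int(total * warmup_frac))
    if step < warm:
        return base * (step + 1) / warm
    return base * max(0.0, (total - step) / max(1, total - warm))


def train_end_model(
    dataset: ProbDataset,
    encoder: HashedWindowEncoder | PrecomputedEncoder | None = None,
    config: EndModelConfig | None = None,
) -> SequenceClassifier:
    """Mini-batch gradient descent on the noise-aware loss over unmasked
    training tokens, with a 10%-warmup linear-decay learning-rate schedule
    and early stopping on validation token F1. Deterministic given the seed.
    """
    encoder = encoder or HashedWindowEncoder()
    config = config or EndModelConfig()
    K = dataset.soft_labels[0].shape[1] if dataset.soft_labels else 2

    Xs, Ys, Ms, is_train = [], [], [], []
    for seq, y, mask, split in zip(dataset.sequences, dataset.soft_labels, dataset.masks, dataset.splits):
        if len(seq) == 0:
            continue
        Xs.append(encoder.encode(seq))
        Ys.append(y)
        Ms.append(mask)
        is_train.append(np.full(len(seq), split == "train"))
    X = sp.vstack(Xs).tocsr()
    Y = np.concatenate(Ys)
    mask = np.concatenate(Ms)
    is_train = np.concatenate(is_train)

    train_rows = np.flatnonzero(is_train & mask)
    if train_rows.size == 0:
        raise ValueError("no unmasked training tokens")
    valid_rows = np.flatnonzero(~is_train & mask)

    dim = X.shape[1]
    W = np.zeros((dim, K))
    b = np.zeros(K)
    rng = np.random.default_rng(config.seed)

    n_batches = int(np.ceil(train_rows.size / config.batch_size))
    total_steps = config.epochs * n_batches
    step = 0
    best = (-1.0, W.copy(), b.copy())
    stale = 0
    Xtr = X[train_rows]
    Ytr = Y[train_rows]
    for epoch in range(config.epochs):
        order = rng.permutation(train_rows.size)
        for bi in range(n_batches):
            idx = order[bi * config.batch_size : (bi + 1) * config.batch_size]
            Xb = Xtr[idx]
            Yb = Ytr[idx]
            z = Xb @ W + b
            z -= z.max(axis=1, keepdims=True)
            e = np.exp(z)
            P = e / e.sum(axis=1, keepdims=True)
            G = (P - Yb) / len(idx)
            lr = _lr_at(step, total_steps, config.lr, config.warmup_frac)
            W -= lr * (Xb.T @ G + config.l2 * W)
            b -= lr * G.sum(axis=0)
            step += 1
        if valid_rows.size:
            Pv = X[valid_rows] @ W + b
            pred = Pv.argmax(axis=1)
            gold = Y[valid_rows].argmax(axis=1)
            f1 = _token_f1(pred, gold, K)
            if f1 > best[0] + 1e-12:
                best = (f1, W.copy(), b.copy())
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if valid_rows.size and best[0] >= 0:
        W, b = best[1], best[2]
    return SequenceClassifier(W=W, b=b, encoder=encoder, n_classes=K)


def predict_tags(model: SequenceClassifier, seq: TokenSequence, spans: list[Span] | None = None):
    """NER mode: per-token argmax as IO tags (plus distributions).

    Span mode (``spans`` given): classify only each span's head word (its
    first token), returning one label per span.
    """
    probs = model.predict_proba(seq)
    if spans is not None:
        heads = [sp.token_start for sp in spans]
        labels = probs[heads].argmax(axis=1) if heads else np.zeros(0, dtype=int)
        return labels, probs[heads] if heads else probs[:0]
    hard = probs.argmax(axis=1) if len(seq) else np.zeros(0, dtype=int)
    tags = ["O" if c == 0 else f"I-{c}" for c in hard]
    return TagSequence(tags, IO), probs
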