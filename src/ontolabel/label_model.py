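"""Data-programming label model: learn per-source accuracies from agreement
statistics, without ground truth, and produce consensus probabilistic labels.

The model treats each labeling function (LF) as conditionally independent
given the true label, with a symmetric class-conditional accuracy. On a +/-1
encoding of a one-vs-rest view of class c, the accuracy a_i = E[lambda_i Y]
is not observable, but the pairwise agreement moment
E[lambda_i lambda_j] = a_i a_j is; accuracies are then recovered up to a
global sign from triplets of sources:

    |a_i| = sqrt(| M_ij * M_ik / M_jk |)

aggregated by the median over valid (j, k) pairs. Relative signs come from
the signs of the moments; the global sign is fixed by assuming sources are
better than random on average. Estimates can optionally be refined by
deterministic L-BFGS on the pairwise moment-matching least-squares objective
with an L2 pull toward a uniform accuracy prior.

Posteriors combine votes naive-Bayes style: an LF voting the hypothesized
class contributes its accuracy, a non-abstaining disagreeing LF contributes
(1 - accuracy) / (K - 1) (errors spread uniformly over wrong classes), and
abstains contribute nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .corpus import ABSTAIN
from .labeling import LabelMatrix

logger = logging.getLogger(__name__)


@dataclass
class LabelModelConfig:
    n_classes: int = 2
    prior_acc: float = 0.7  # uniform accuracy prior, probability scale
    clamp_eps: float = 0.01
    min_overlap: int = 25  # co-votes needed for a reliable pairwise moment
    triplet_denom_guard: float = 1e-3
    refine: bool = True
    l2: float = 0.05  # pull toward the prior during refinement
    class_prior: tuple | None = None  # estimated from majority vote if None
    default_class: int = 0
    seed: int = 0


@dataclass
class LabelModel:
    """Fitted parameters: per-LF accuracy per class view (probability
    scale), per-LF propensity (non-abstain rate), and the class prior."""

    acc: np.ndarray  # (m, K)
    propensity: np.ndarray  # (m,)
    class_prior: np.ndarray  # (K,)
    lf_names: list[str] = field(default_factory=list)
    config: LabelModelConfig = field(default_factory=LabelModelConfig)


@dataclass
class ProbLabels:
    """Per-unit posterior distributions plus a coverage flag (False where
    every LF abstained)."""

    probs: np.ndarray  # (n, K)
    covered: np.ndarray  # (n,) bool


def _values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, LabelMatrix) else np.asarray(matrix)


# ---------------------------------------------------------------------------
# Majority vote
# ---------------------------------------------------------------------------


def majority_vote(matrix, n_classes: int, default_class: int = 0) -> np.ndarray:
    """Per unit, the mode of non-abstain votes; all-abstain or tied modes
    fall back to ``default_class``."""
    L = _values(matrix)
    if L.size == 0:
        raise ValueError("empty label matrix")
    n = L.shape[0]
    counts = np.zeros((n, n_classes), dtype=np.int64)
    for c in range(n_classes):
        counts[:, c] = (L == c).sum(axis=1)
    top = counts.max(axis=1)
    out = counts.argmax(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    out[(top == 0) | tied] = default_class
    return out


# ---------------------------------------------------------------------------
# Moments and triplet estimation
# ---------------------------------------------------------------------------


def binarize(L: np.ndarray, c: int) -> np.ndarray:
    """One-vs-rest +/-1 view for class c: +1 vote-for-c, -1 vote-for-other,
    0 abstain."""
    B = np.zeros_like(L, dtype=np.float64)
    B[L == c] = 1.0
    B[(L != c) & (L != ABSTAIN)] = -1.0
    return B


def pairwise_moments(B: np.ndarray, min_overlap: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Agreement moments E[lambda_i lambda_j] over units where both LFs vote.

    Returns (M, reliable): M has unit diagonal; entries with fewer than
    ``min_overlap`` co-votes (or none) are flagged unreliable and must be
    excluded from triplets.
    """
    nonzero = (B != 0).astype(np.float64)
    overlap = nonzero.T @ nonzero
    prod = B.T @ B
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(overlap > 0, prod / np.maximum(overlap, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    reliable = overlap >= min_overlap
    np.fill_diagonal(reliable, True)
    return M, reliable


def triplet_accuracies(
    M: np.ndarray,
    reliable: np.ndarray | None = None,
    denom_guard: float = 1e-3,
    clamp_eps: float = 0.01,
) -> np.ndarray:
    """Recover +/-1-scale accuracies a_i from pairwise moments via disjoint
    triplets, median-aggregated; signs from moment signs, global sign chosen
    so the mean accuracy is positive (sources better than random on
    average). Clamped to [-1 + eps, 1 - eps]."""
    m = M.shape[0]
    if reliable is None:
        reliable = np.ones_like(M, dtype=bool)
    mags = np.zeros(m)
    for i in range(m):
        ests = []
        for j in range(m):
            if j == i or not reliable[i, j]:
                continue
            for k in range(j + 1, m):
                if k == i or not reliable[i, k] or not reliable[j, k]:
                    continue
                if abs(M[j, k]) < denom_guard:
                    continue  # division guard: skip degenerate triplet
                ests.append(np.sqrt(abs(M[i, j] * M[i, k] / M[j, k])))
        mags[i] = np.median(ests) if ests else 0.0
    mags = np.minimum(mags, 1.0 - clamp_eps)

    # relative signs from the moment signs against a reference LF
    ref = int(np.argmax(mags))
    signs = np.ones(m)
    for i in range(m):
        if i != ref and reliable[ref, i] and M[ref, i] != 0:
            signs[i] = np.sign(M[ref, i])
    a = signs * mags
    if a.mean() < 0:
        a = -a
    return np.clip(a, -1.0 + clamp_eps, 1.0 - clamp_eps)


def _refine_accuracies(
    a0: np.ndarray, M: np.ndarray, reliable: np.ndarray, prior_a: float, l2: float, clamp_eps: float
) -> np.ndarray:
    """Deterministic L-BFGS on sum_{i<j} (a_i a_j - M_ij)^2 + l2 ||a - prior||^2."""
    m = len(a0)
    iu = np.triu_indices(m, k=1)
    mask = reliable[iu]
    target = M[iu]

    def objective(a: np.ndarray):
        outer = np.outer(a, a)
        resid = (outer[iu] - target) * mask
        val = float((resid**2).sum() + l2 * ((a - prior_a) ** 2).sum())
        # gradient of sum (a_i a_j - M_ij)^2 wrt a
        R = np.zeros((m, m))
        R[iu] = resid
        R = R + R.T
        grad = 2.0 * (R @ a) + 2.0 * l2 * (a - prior_a)
        return val, grad

    res = minimize(
        objective, a0, jac=True, method="L-BFGS-B",
        bounds=[(-1.0 + clamp_eps, 1.0 - clamp_eps)] * m,
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite refinement objective; moment matrix:\n{M}")
    return np.clip(res.x, -1.0 + clamp_eps, 1.0 - clamp_eps)


# ---------------------------------------------------------------------------
# Fit / posterior / predict
# ---------------------------------------------------------------------------


def fit_label_model(matrix, config: LabelModelConfig | None = None, lf_names: list[str] | None = None) -> LabelModel:
    """Estimate per-LF accuracies (one-vs-rest per class) from agreement
    moments, the class prior from majority-vote frequencies, and LF
    propensities. Deterministic given inputs."""
    config = config or LabelModelConfig()
    L = _values(matrix)
    n, m = L.shape
    K = config.n_classes
    prior_a = 2.0 * config.prior_acc - 1.0

    acc = np.full((m, K), config.prior_acc)
    if m < 3:
        warnings.warn("fewer than 3 LFs: falling back to the uniform accuracy prior")
    else:
        for c in range(K):
            B = binarize(L, c)
            if not (B != 0).any():
                continue
            M, reliable = pairwise_moments(B, config.min_overlap)
            usable = (reliable.sum(axis=1) - 1) >= 2
            if usable.sum() < 3:
                warnings.warn(f"class {c}: fewer than 3 LFs with reliable moments; using prior")
                a = np.full(m, prior_a)
            else:
                a = triplet_accuracies(M, reliable, config.triplet_denom_guard, config.clamp_eps)
                a[~usable] = prior_a
                if config.refine:
                    a = _refine_accuracies(a, M, reliable & usable[:, None] & usable[None, :],
                                           prior_a, config.l2, config.clamp_eps)
            acc[:, c] = np.clip((1.0 + a) / 2.0, config.clamp_eps, 1.0 - config.clamp_eps)

    if config.class_prior is not None:
        class_prior = np.asarray(config.class_prior, dtype=float)
    else:
        mv = majority_vote(L, K, config.default_class)
        class_prior = np.bincount(mv, minlength=K) + 1.0  # add-one smoothing
    class_prior = class_prior / class_prior.sum()

    propensity = (L != ABSTAIN).mean(axis=0)
    names = lf_names or (matrix.lf_names if isinstance(matrix, LabelMatrix) else [f"lf{i}" for i in range(m)])
    return LabelModel(acc=acc, propensity=propensity, class_prior=class_prior,
                      lf_names=list(names), config=config)


def posterior(model: LabelModel, matrix) -> ProbLabels:
    """P(Y | Lambda) under the conditional-independence accuracy model.

    Per unit: P(y) proportional to prior(y) * prod over non-abstaining LFs of
    [acc_i(y) if vote == y else (1 - acc_i(y)) / (K - 1)]. Units where all
    LFs abstain get the class prior and covered=False.
    """
    L = _values(matrix)
    n, m = L.shape
    K = model.config.n_classes
    logp = np.tile(np.log(model.class_prior), (n, 1))
    for c in range(K):
        log_match = np.log(model.acc[:, c])
        log_miss = np.log((1.0 - model.acc[:, c]) / max(K - 1, 1))
        match = L == c
        miss = (L != c) & (L != ABSTAIN)
        logp[:, c] += match @ log_match + miss @ log_miss
    logp -= logsumexp(logp, axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    covered = (L != ABSTAIN).any(axis=1)
    return ProbLabels(probs=probs, covered=covered)


def predict(model: LabelModel, matrix, default_class: int | None = None) -> np.ndarray:
    """Hard labels: argmax posterior; exact ties and uncovered units fall
    back to the default class. Invariant to LF column order."""
    if default_class is None:
        default_class = model.config.default_class
    pl = posterior(model, matrix)
    out = pl.probs.argmax(axis=1)
    top = pl.probs.max(axis=1)
    tied = (pl.probs == top[:, None]).sum(axis=1) > 1
    out[tied | ~pl.covered] = default_class
    return out


def posterior_brute_force(
    acc: np.ndarray, class_prior: np.ndarray, votes: np.ndarray, propensity: np.ndarray | None = None
) -> np.ndarray:
    """Independent oracle: enumerate P(y, lambda) for one vote configuration
    under the generative model (abstain w.p. 1 - propensity; correct vote
    w.p. accuracy; errors uniform over wrong classes) and normalize.

    Used to verify ``posterior`` — it shares no code with it.
    """
    m, K = acc.shape
    if propensity is None:
        propensity = np.ones(m)
    joint = np.zeros(K)
    for y in range(K):
        p = class_prior[y]
        for i in range(m):
            v = votes[i]
            if v == ABSTAIN:
                # the abstain factor (1 - propensity) is constant in y, so it
                # cancels in the normalization; skipping it also keeps
                # zero-probability configurations (propensity 1) well-defined
                continue
            elif v == y:
                p *= propensity[i] * acc[i, y]
            else:
                p *= propensity[i] * (1.0 - acc[i, y]) / max(K - 1, 1)
        joint[y] = p
    return joint / joint.sum()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_label_model(model: LabelModel, path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "acc": model.acc.tolist(),
                "propensity": model.propensity.tolist(),
                "class_prior": model.class_prior.tolist(),
                "lf_names": model.lf_names,
                "n_classes": model.config.n_classes,
            },
            fh,
            indent=1,
        )


def load_label_model(path) -> LabelModel:
    import json

    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    cfg = LabelModelConfig(n_classes=d["n_classes"])
    return LabelModel(
        acc=np.array(d["acc"]),
        propensity=np.array(d["propensity"]),
        class_prior=np.array(d["class_prior"]),
        lf_names=d["lf_names"],
        config=cfg,
    )
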