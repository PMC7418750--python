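"""Scoring: exact-span precision/recall/F1 for NER, micro-averaged token
metrics for span tasks, and method-comparison reports with Wilcoxon
signed-rank significance."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .corpus import Span, TagSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 as proportions (report x100), with supports."""

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int

    @staticmethod
    def from_counts(tp: int, fp: int, fn: int) -> "PRF":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return PRF(p, r, f1, tp, fp, fn)


def exact_span_prf(gold: list[Span], pred: list[Span], known_refs: set | None = None) -> PRF:
    """Exact span matching: a prediction counts iff (doc, sentence, start,
    end, class) all agree with a gold span."""
    if known_refs is not None:
        for sp in list(gold) + list(pred):
            if (sp.doc_ref, sp.sent_index) not in known_refs:
                raise ValueError(f"span references unknown sequence: {sp}")
    gset = {(s.doc_ref, s.sent_index, s.token_start, s.token_end, s.label) for s in gold}
    pset = {(s.doc_ref, s.sent_index, s.token_start, s.token_end, s.label) for s in pred}
    tp = len(gset & pset)
    return PRF.from_counts(tp, len(pset - gset), len(gset - pset))


def token_prf(
    gold: np.ndarray | list[int],
    pred: np.ndarray | list[int],
    labels: list[int] | None = None,
) -> tuple[dict[int, PRF], PRF]:
    """Per-class token PRF plus the micro aggregate (pooled counts over the
    scored classes). With all classes scored and single-label tokens, micro
    F1 equals accuracy."""
    gold = np.asarray(gold)
    pred = np.asarray(pred)
    if gold.shape != pred.shape:
        raise ValueError(f"length mismatch: {gold.shape} vs {pred.shape}")
    if labels is None:
        labels = sorted(set(gold.tolist()) | set(pred.tolist()))
    per_class: dict[int, PRF] = {}
    TP = FP = FN = 0
    for c in labels:
        tp = int(((gold == c) & (pred == c)).sum())
        fp = int(((gold != c) & (pred == c)).sum())
        fn = int(((gold == c) & (pred != c)).sum())
        per_class[c] = PRF.from_counts(tp, fp, fn)
        TP, FP, FN = TP + tp, FP + fp, FN + fn
    return per_class, PRF.from_counts(TP, FP, FN)


def tags_token_prf(gold: TagSequence, pred: TagSequence, labels=None) -> tuple[dict, PRF]:
    to_int = lambda t: 0 if t == "O" else int(t.split("-", 1)[1])
    return token_prf([to_int(t) for t in gold.tags], [to_int(t) for t in pred.tags], labels)


def compare_report(
    scores: dict[str, list[float]],
    pairs: list[tuple[str, str]] | None = None,
    min_replicates: int = 5,
) -> pd.DataFrame:
    """Per-method mean +/- SD of F1 plus paired two-sided Wilcoxon
    signed-rank p-values (Pratt zero handling) between method pairs.

    Deterministic methods may be given a single replicate; identical paired
    scores yield p = 1 by convention. Fewer than ``min_replicates`` paired
    replicates omits significance with a warning.
    """
    rows = []
    for name, vals in scores.items():
        vals = np.asarray(list(vals), dtype=float)
        sd = 0.0
        if len(vals) > 1 and np.ptp(vals) > 0:
            sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "method": name,
                "mean_f1": float(np.mean(vals)),
                "sd_f1": sd,
                "n_runs": len(vals),
            }
        )
    table = pd.DataFrame(rows)

    if pairs is None:
        pairs = list(combinations(scores, 2))
    pvals = {}
    for a, b in pairs:
        xa, xb = scores[a], scores[b]
        if len(xa) != len(xb) or len(xa) < min_replicates:
            warnings.warn(f"fewer than {min_replicates} paired replicates for ({a}, {b}); significance omitted")
            continue
        diffs = np.asarray(xa) - np.asarray(xb)
        if np.all(diffs == 0):
            pvals[(a, b)] = 1.0
            continue
        stat = wilcoxon(xa, xb, zero_method="pratt", alternative="two-sided")
        pvals[(a, b)] = float(stat.pvalue)
    table.attrs["wilcoxon_p"] = pvals
    return table
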