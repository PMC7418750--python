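"""Synthetic-scale study harnesses.

Each function sets up a seeded synthetic world, runs one part of the
pipeline, and measures it against the known ground truth. The tests and the
reproduction script both call these, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .end_model import EndModelConfig, HashedWindowEncoder, build_training_set, predict_tags, train_end_model
from .evaluation import token_prf
from .label_model import (
    LabelModel,
    LabelModelConfig,
    fit_label_model,
    majority_vote,
    posterior,
    posterior_brute_force,
    predict,
)
from .labeling import SemanticTypeLF, build_label_matrix
from .ontology import build_type_distribution
from .pipeline import tags_to_int
from .synthetic import (
    SourceSpec,
    World,
    WorldSpec,
    build_world,
    calibrated_precision_source,
    generate_corpus,
    generate_label_matrix,
    generate_sources,
    span_disagreement_fixture,
)


def make_injected_model(acc: np.ndarray, class_prior, n_classes: int) -> LabelModel:
    """A label model with known (injected) accuracies — skips fitting."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim == 1:
        acc = np.repeat(acc[:, None], n_classes, axis=1)
    return LabelModel(
        acc=acc,
        propensity=np.ones(acc.shape[0]),
        class_prior=np.asarray(class_prior, dtype=float),
        lf_names=[f"lf{i}" for i in range(acc.shape[0])],
        config=LabelModelConfig(n_classes=n_classes),
    )


def bayes_oracle_deviation(n_classes: int = 3, seed: int = 0) -> float:
    """Max |posterior - brute-force enumeration| over every vote
    configuration of 3 LFs, with randomly drawn injected accuracies."""
    rng = np.random.default_rng(seed)
    acc = rng.uniform(0.55, 0.95, size=(3, n_classes))
    prior = rng.dirichlet(np.ones(n_classes) * 5)
    prop = rng.uniform(0.5, 1.0, size=3)
    model = make_injected_model(acc, prior, n_classes)
    worst = 0.0
    for votes in itertools.product(range(-1, n_classes), repeat=3):
        v = np.asarray(votes)
        p_model = posterior(model, v[None, :]).probs[0]
        p_oracle = posterior_brute_force(acc, prior, v, prop)
        worst = max(worst, float(np.abs(p_model - p_oracle).max()))
    return worst


def accuracy_recovery(
    n_seeds: int = 20, m: int = 8, n: int = 10_000, abstain: float = 0.3, seed: int = 0
) -> list[float]:
    """Median absolute accuracy-estimation error per seeded simulation
    (true accuracies drawn uniformly in [0.55, 0.95])."""
    errs = []
    for k in range(n_seeds):
        run_seed = seed + k
        rng = np.random.default_rng(run_seed)
        accs = rng.uniform(0.55, 0.95, size=m)
        matrix, _ = generate_label_matrix(n, list(accs), [abstain] * m, [0.5, 0.5], seed=run_seed)
        model = fit_label_model(matrix, LabelModelConfig(n_classes=2))
        errs.append(float(np.median(np.abs(model.acc[:, 1] - accs))))
    return errs


@dataclass
class _TextRun:
    mv_f1: float
    lm_f1: float
    noisy_precision: float


def _gold_flat(docs, gold_tags) -> np.ndarray:
    return np.concatenate(
        [tags_to_int(gold_tags[(d.doc_id, s.sent_index)]) for d in docs for s in d.sentences]
    )


def heterogeneity_run(seed: int, n_sentences: int = 400, target_precision: float = 0.65) -> _TextRun:
    """One mixed-quality simulation: three clean mid-recall sources plus one
    high-recall source calibrated to ~65% word-level precision. Majority
    vote treats them equally; the label model learns the noisy source's
    accuracy from disagreement alone."""
    spec = WorldSpec(n_classes=2, seed=seed)
    world = build_world(spec)
    docs, _, gold_tags = generate_corpus(world, n_sentences, seed=seed + 1)
    clean = generate_sources(
        world, [SourceSpec(recall=0.8, bg_coverage=0.5, name=f"clean{i}") for i in range(3)], seed=seed + 2
    )
    noisy = calibrated_precision_source(world, docs, target_precision, recall=1.0, seed=seed + 3)
    sources = clean + [noisy]
    lfs = [
        SemanticTypeLF(t.name, t, build_type_distribution([t], 2), unmatched="abstain") for t in sources
    ]
    matrix = build_label_matrix(lfs, docs)
    gold = _gold_flat(docs, gold_tags)
    mv = majority_vote(matrix, 2)
    model = fit_label_model(matrix, LabelModelConfig(n_classes=2))
    lm = predict(model, matrix)
    _, mv_prf = token_prf(gold, mv, labels=[1])
    _, lm_prf = token_prf(gold, lm, labels=[1])
    col = matrix.values[:, matrix.lf_names.index(noisy.name)]
    n_votes = int((col == 1).sum())
    prec = float(((col == 1) & (gold == 1)).sum() / n_votes) if n_votes else 0.0
    return _TextRun(mv_prf.f1, lm_prf.f1, prec)


@dataclass
class _GenRun:
    lm_f1: float
    ws_f1: float
    heldout_recall: float
    lm_heldout_recall: float
    n_heldout_tokens: int


def generalization_run(seed: int, n_sentences: int = 600, covered_frac: float = 0.8) -> _GenRun:
    """Hold out 20% of the entity lexicon from every label source; the label
    model cannot tag those occurrences (all LFs abstain), while the end
    model can generalize to them through character/context features."""
    rng = np.random.default_rng(seed)
    spec = WorldSpec(n_classes=2, seed=seed)
    world = build_world(spec)
    all_terms = sorted(world.all_terms().items())
    order = rng.permutation(len(all_terms))
    n_known = int(covered_frac * len(all_terms))
    known = [all_terms[i][0] for i in order[:n_known]]
    docs, _, gold_tags = generate_corpus(world, n_sentences, seed=seed + 1)
    covered_world = World(spec, {1: known}, {}, world.background)
    sources = generate_sources(
        covered_world,
        [SourceSpec(recall=0.9, bg_coverage=0.5, name=f"s{i}") for i in range(3)],
        seed=seed + 2,
    )
    lfs = [
        SemanticTypeLF(t.name, t, build_type_distribution([t], 2), unmatched="abstain") for t in sources
    ]
    matrix = build_label_matrix(lfs, docs)
    gold = _gold_flat(docs, gold_tags)
    model = fit_label_model(matrix, LabelModelConfig(n_classes=2))
    problabels = posterior(model, matrix)
    lm_pred = predict(model, matrix)
    dataset = build_training_set(docs, problabels, matrix.row_index, valid_frac=0.15, seed=seed)
    clf = train_end_model(dataset, HashedWindowEncoder(dim=2**15), EndModelConfig(epochs=15, seed=seed))
    ws_pred = np.concatenate(
        [tags_to_int(predict_tags(clf, s)[0]) for d in docs for s in d.sentences]
    )
    heldout_pos = ~problabels.covered & (gold == 1)
    n_held = int(heldout_pos.sum())
    ws_rec = float((ws_pred[heldout_pos] == 1).mean()) if n_held else 0.0
    lm_rec = float((lm_pred[heldout_pos] == 1).mean()) if n_held else 0.0
    _, lm_prf = token_prf(gold, lm_pred, labels=[1])
    _, ws_prf = token_prf(gold, ws_pred, labels=[1])
    return _GenRun(lm_prf.f1, ws_prf.f1, ws_rec, lm_rec, n_held)


def span_fixture_outcome() -> dict:
    """The partial-coverage worked example: does majority vote truncate the
    three-token entity, and does an accuracy-weighted label model recover
    it?"""
    docs, terms, gold, n_classes = span_disagreement_fixture()
    lfs = [
        SemanticTypeLF(t.name, t, build_type_distribution([t], n_classes), unmatched="negative")
        for t in terms
    ]
    matrix = build_label_matrix(lfs, docs)
    mv = majority_vote(matrix, n_classes)
    acc = np.array([0.9, 0.9, 0.6, 0.6])  # full-term sources are more reliable
    model = make_injected_model(acc, [0.9, 0.1], n_classes)
    lm = predict(model, matrix)
    span = gold["example_doc"][0]
    span_tokens = slice(span.token_start, span.token_end)
    return {
        "mv_tokens_tagged": int((mv[span_tokens] == 1).sum()),
        "lm_tokens_tagged": int((lm[span_tokens] == 1).sum()),
        "span_length": span.token_end - span.token_start,
        "mv_truncates": bool((mv[span_tokens] == 1).sum() < span.token_end - span.token_start),
        "lm_recovers": bool((lm[span_tokens] == 1).all()),
        "false_positive_tokens": int((mv == 1).sum() + (lm == 1).sum())
        - int((mv[span_tokens] == 1).sum() + (lm[span_tokens] == 1).sum()),
    }
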