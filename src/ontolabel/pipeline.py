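"""End-to-end pipeline runner: label -> fit -> (optional) train -> eval.

Configuration is a single YAML file; every artifact is stamped with the
config hash and seed so reruns are byte-reproducible. The label model can
serve as the final classifier (``end_model.enabled: false``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .corpus import IO, Document, Span, TagSequence, io_to_bio, read_conll, read_jsonl_corpus, tags_to_spans, write_conll
from .end_model import EndModelConfig, HashedWindowEncoder, build_training_set, predict_tags, train_end_model
from .label_model import (
    LabelModelConfig,
    ProbLabels,
    fit_label_model,
    majority_vote,
    posterior,
    predict,
    save_label_model,
)
from .labeling import LabelMatrix, PatternLF, SemanticTypeLF, build_label_matrix
from .ontology import Terminology, build_type_distribution, load_terminology, partition_sources, rank_by_coverage

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    corpus: str = ""
    terminologies: list[str] = field(default_factory=list)
    class_map: dict[str, int] = field(default_factory=dict)
    n_classes: int = 2
    gold: str | None = None
    lf: dict = field(default_factory=dict)  # unmatched, slot_patterns, patterns: [...]
    label_model: dict = field(default_factory=dict)
    end_model: dict = field(default_factory=dict)  # enabled, lr, epochs, dim, ...
    valid_frac: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cm = raw.get("class_map", {})
        if isinstance(cm, str):
            with open(cm, encoding="utf-8") as fh:
                cm = yaml.safe_load(fh) or {}
        raw["class_map"] = {str(k): int(v) for k, v in cm.items()}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def validate(self) -> None:
        for p in [self.corpus, *self.terminologies, *( [self.gold] if self.gold else [] )]:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_lfs(config: PipelineConfig, terminologies: list[Terminology]):
    """Instantiate LF templates from loaded terminologies plus any
    pattern rules in the config."""
    unmatched = config.lf.get("unmatched", "abstain")
    slot = bool(config.lf.get("slot_patterns", True))
    # each source votes from its own type assignments; disagreement between
    # sources is what the label model learns from
    lfs = [
        SemanticTypeLF(t.name, t, build_type_distribution([t], config.n_classes),
                       unmatched=unmatched, slot_patterns=slot)
        for t in terminologies
    ]
    for pat in config.lf.get("patterns", []):
        dictionary = None
        if "dictionary" in pat:
            dictionary = {tuple(term.split()) for term in pat["dictionary"]}
        lfs.append(
            PatternLF(
                pat["name"],
                label=int(pat["label"]),
                regex=pat.get("regex"),
                dictionary=dictionary,
                unmatched=pat.get("unmatched", "abstain"),
            )
        )
    return lfs


def hard_labels_to_tags(labels: np.ndarray, row_index: list[tuple]) -> dict[tuple[str, int], TagSequence]:
    """Group per-token hard labels (corpus order) into IO tag sequences."""
    out: dict[tuple[str, int], list[str]] = {}
    for (doc_id, sent, tok), c in zip(row_index, labels):
        out.setdefault((doc_id, sent), []).append("O" if c == 0 else f"I-{int(c)}")
    return {k: TagSequence(v, IO) for k, v in out.items()}


def align_gold(docs: list[Document], conll: list[tuple[list[str], TagSequence]]) -> dict[tuple[str, int], TagSequence]:
    keys = [(d.doc_id, s.sent_index) for d in docs for s in d.sentences]
    if len(keys) != len(conll):
        raise ValueError(f"gold has {len(conll)} sentences, corpus has {len(keys)}")
    out = {}
    for key, (toks, tags) in zip(keys, conll):
        out[key] = tags
    return out


def tags_to_int(tags: TagSequence) -> list[int]:
    return [0 if t == "O" else int(t.split("-", 1)[1]) for t in tags.tags]


def _score_tags(
    gold: dict[tuple[str, int], TagSequence],
    pred: dict[tuple[str, int], TagSequence],
    n_classes: int,
) -> dict[str, float]:
    """Token micro-F1 over entity classes plus exact-span F1 (after IO->BIO)."""
    g_flat: list[int] = []
    p_flat: list[int] = []
    g_spans: list[Span] = []
    p_spans: list[Span] = []
    for key in gold:
        gt, pt = gold[key], pred[key]
        g_flat.extend(tags_to_int(gt))
        p_flat.extend(tags_to_int(pt))
        doc_id, sent = key
        g_spans.extend(tags_to_spans(io_to_bio(gt), doc_id, sent))
        p_spans.extend(tags_to_spans(io_to_bio(pt), doc_id, sent))
    _, micro = evaluation.token_prf(g_flat, p_flat, labels=list(range(1, n_classes)))
    span = evaluation.exact_span_prf(g_spans, p_spans)
    return {
        "token_f1": micro.f1,
        "token_precision": micro.precision,
        "token_recall": micro.recall,
        "span_f1": span.f1,
        "span_precision": span.precision,
        "span_recall": span.recall,
    }


def save_problabels(path, problabels: ProbLabels, row_index: list[tuple]) -> None:
    """JSONL per sentence: {doc_id, sent, probs: [[p0..pk], ...]}."""
    by_sent: dict[tuple[str, int], list[list[float]]] = {}
    order: list[tuple[str, int]] = []
    for (doc_id, sent, tok), p in zip(row_index, problabels.probs):
        key = (doc_id, sent)
        if key not in by_sent:
            by_sent[key] = []
            order.append(key)
        by_sent[key].append([round(float(x), 6) for x in p])
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, sent in order:
            fh.write(json.dumps({"doc_id": doc_id, "sent": sent, "probs": by_sent[(doc_id, sent)]}) + "\n")


def run_pipeline(config: PipelineConfig, outdir, stop_after: str | None = None) -> dict:
    """Execute label -> fit -> train -> eval, writing artifacts under
    ``outdir``; halts with the failing stage's name on error."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    stage = "label"
    try:
        t0 = time.perf_counter()
        docs = read_jsonl_corpus(config.corpus)
        terminologies = [
            load_terminology(p, config.class_map, name=Path(p).stem) for p in config.terminologies
        ]
        lfs = build_lfs(config, terminologies)
        matrix = build_label_matrix(lfs, docs)
        matrix.save(outdir / "label_matrix")
        artifacts += [str(outdir / "label_matrix.npz"), str(outdir / "label_matrix.rows.tsv")]
        report["stages"]["label"] = {"n_tokens": matrix.n, "n_lfs": matrix.m, "seconds": time.perf_counter() - t0}
        if stop_after == "label":
            raise StopIteration

        stage = "fit"
        t0 = time.perf_counter()
        lm_cfg = LabelModelConfig(n_classes=config.n_classes, seed=config.seed, **config.label_model)
        model = fit_label_model(matrix, lm_cfg)
        save_label_model(model, outdir / "label_model.json")
        mv = majority_vote(matrix, config.n_classes)
        lm = predict(model, matrix)
        problabels = posterior(model, matrix)
        save_problabels(outdir / "prob_labels.jsonl", problabels, matrix.row_index)
        mv_tags = hard_labels_to_tags(mv, matrix.row_index)
        lm_tags = hard_labels_to_tags(lm, matrix.row_index)
        write_conll(outdir / "pred_mv.conll", docs, mv_tags)
        write_conll(outdir / "pred_lm.conll", docs, lm_tags)
        artifacts += [str(outdir / p) for p in ("label_model.json", "prob_labels.jsonl", "pred_mv.conll", "pred_lm.conll")]
        report["stages"]["fit"] = {"accuracies": model.acc[:, 1].round(4).tolist(), "seconds": time.perf_counter() - t0}
        if stop_after == "fit":
            raise StopIteration

        stage = "train"
        final_tags = lm_tags
        use_end = bool(config.end_model.get("enabled", True))
        if use_end and stop_after != "no-train":
            t0 = time.perf_counter()
            dataset = build_training_set(docs, problabels, matrix.row_index, config.valid_frac, config.seed)
            em_kwargs = {k: v for k, v in config.end_model.items() if k not in ("enabled", "dim", "window")}
            em_cfg = EndModelConfig(seed=config.seed, **em_kwargs)
            encoder = HashedWindowEncoder(
                dim=int(config.end_model.get("dim", 2**15)), window=int(config.end_model.get("window", 2))
            )
            clf = train_end_model(dataset, encoder, em_cfg)
            ws_tags = {}
            for doc in docs:
                for sent in doc.sentences:
                    tags, _ = predict_tags(clf, sent)
                    ws_tags[(doc.doc_id, sent.sent_index)] = tags
            write_conll(outdir / "pred_ws.conll", docs, ws_tags)
            artifacts.append(str(outdir / "pred_ws.conll"))
            final_tags = ws_tags
            report["stages"]["train"] = {"seconds": time.perf_counter() - t0}
        if stop_after == "train":
            raise StopIteration

        stage = "eval"
        if config.gold:
            gold = align_gold(docs, read_conll(config.gold))
            metrics = {"mv": _score_tags(gold, mv_tags, config.n_classes),
                       "lm": _score_tags(gold, lm_tags, config.n_classes)}
            if use_end and "pred_ws.conll" in " ".join(artifacts):
                metrics["ws"] = _score_tags(gold, final_tags, config.n_classes)
            report["stages"]["eval"] = metrics
            pd.DataFrame(metrics).T.to_csv(outdir / "report.tsv", sep="\t")
            artifacts.append(str(outdir / "report.tsv"))
    except StopIteration:
        pass
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}; artifacts so far: {artifacts}") from err

    report["artifacts"] = artifacts
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def partition_sweep(
    terminologies: list[Terminology],
    docs: list[Document],
    gold_tags: dict[tuple[str, int], TagSequence],
    n_classes: int,
    s_values: list[int],
    lm_config: LabelModelConfig | None = None,
    unmatched: str = "negative",
) -> pd.DataFrame:
    """Score majority vote and the label model for each partition size s.

    Terminologies are ranked by corpus coverage; for each s the top-s stay
    individual LFs and the rest merge into one. Reports raw F1 and F1 minus
    the best majority-vote score; MV scores do not depend on the label-model
    config.
    """
    ranked = rank_by_coverage(terminologies, docs)
    rows = []
    per_s: dict[int, dict] = {}
    for s in s_values:
        part = partition_sources(ranked, s)
        sources = part.label_sources()
        cfg = PipelineConfig(n_classes=n_classes, lf={"unmatched": unmatched})
        lfs = build_lfs(cfg, sources)
        matrix = build_label_matrix(lfs, docs)
        mv = majority_vote(matrix, n_classes)
        mv_scores = _score_tags(gold_tags, hard_labels_to_tags(mv, matrix.row_index), n_classes)
        lm_cfg = lm_config or LabelModelConfig(n_classes=n_classes)
        model = fit_label_model(matrix, lm_cfg)
        lm = predict(model, matrix)
        lm_scores = _score_tags(gold_tags, hard_labels_to_tags(lm, matrix.row_index), n_classes)
        per_s[s] = {"mv": mv_scores["token_f1"], "lm": lm_scores["token_f1"]}
    best_mv = max(v["mv"] for v in per_s.values())
    for s in s_values:
        rows.append(
            {
                "s": s,
                "mv_token_f1": per_s[s]["mv"],
                "lm_token_f1": per_s[s]["lm"],
                "lm_minus_best_mv": per_s[s]["lm"] - best_mv,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["best_s"] = int(table.loc[table["lm_token_f1"].idxmax(), "s"])
    table.attrs["best_mv"] = best_mv
    return table
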