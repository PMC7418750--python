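# ontolabel

Weakly supervised entity classification for (bio)medical text, driven by
ontologies instead of hand-labeled data.

Hand-labeling clinical corpora is slow, expensive, and hard to share.
`ontolabel` builds word-level entity classifiers from *label sources you
already have* — terminologies with semantic-type assignments, synonym sets,
cue-phrase rules — by (1) turning each source into a labeling function that
votes on every word (or abstains), (2) denoising the resulting vote matrix
with a data-programming label model that learns each source's accuracy
*without any ground truth*, and (3) optionally training a discriminative
sequence classifier on the resulting probabilistic labels so the final model
generalizes beyond dictionary coverage.

Because real medical terminologies (UMLS and friends) are license-gated, the
package ships a seeded synthetic-world generator that emulates their
statistical structure — multi-token terms, synonym/abbreviation groups,
sources of heterogeneous recall and precision — so the entire pipeline runs,
and is tested, with no downloads.

## The model

For each word, m labeling functions emit votes λ ∈ {−1, 0, …, k} (−1 =
abstain, 0 = not-an-entity). On a ±1 encoding of the one-vs-rest view of a
class, a source's accuracy aᵢ = E[λᵢ·Y] is not observable without labels,
but under conditionally independent noise the pairwise agreement rate is:

    E[λᵢ λⱼ] = aᵢ aⱼ

so accuracies are recoverable (up to one global sign, fixed by assuming
sources beat random guessing on average) from triplets of sources:

    |aᵢ| = sqrt( |Mᵢⱼ · Mᵢₖ / Mⱼₖ| ),   Mᵢⱼ = empirical E[λᵢ λⱼ]

aggregated by the median over valid (j, k) pairs and optionally refined by
least-squares moment matching. The posterior then combines votes
naive-Bayes style — a vote for class y contributes aᵢ, a disagreeing vote
(1−aᵢ)/(k′−1), an abstain nothing — which is what lets two accurate sources
that know a full multi-token term outvote two partial sources that truncate
it, where equal-weight majority voting ties and fails.

The end model minimizes the noise-aware loss, i.e. the expected
cross-entropy under the soft labels ŷ:

    L = − Σ_y ŷ(y) · log p_w(y | x)

averaged over tokens where at least one labeling function voted (all-abstain
tokens are masked out of the loss).

## Worked example

Generate a synthetic world and run the full pipeline:

```bash
ontolabel simulate --out demo --seed 7 --n-sentences 300 --n-sources 4 --source-recall 0.7
# wrote 60 docs, 149 gold spans to demo

cat > demo/config.yaml <<'YAML'
corpus: demo/corpus.jsonl
terminologies:
  - demo/terminology_src0.tsv
  - demo/terminology_src1.tsv
  - demo/terminology_src2.tsv
  - demo/terminology_src3.tsv
class_map: {"0": 0, "1": 1}
n_classes: 2
gold: demo/gold.conll
lf: {unmatched: abstain}
end_model: {enabled: true, epochs: 10}
seed: 7
YAML

ontolabel run --config demo/config.yaml --out demo/run
cat demo/run/report.tsv
```

which prints (token metrics are micro-F1 over entity classes; span metrics
are exact-match after IO→BIO conversion):

```
        token_f1  token_precision  token_recall  span_f1  span_precision  span_recall
mv      1.0       1.0              1.0           1.0      1.0             1.0
lm      1.0       1.0              1.0           1.0      1.0             1.0
ws      0.934...  1.0              0.877...      0.871... 0.931...        0.818...
```

Four clean sources at 0.7 recall each union to near-complete coverage, so
majority vote (mv) and the label model (lm) are both perfect here; the
feature-based end model (ws) trades a little recall for generalization. The
interesting regime is heterogeneous source quality — mix in a high-recall
source with ~65% word precision and majority vote degrades while the label
model learns to discount it (that comparison is exactly what
`scripts/acceptance.py` measures). `ontolabel sweep` scores every partition
size s (top-s terminologies individual, the rest merged) to pick how many
sources to model separately, and `ontolabel run --no-end-model` uses the
label model itself as the final classifier.

## Layout

| module | what it does |
| --- | --- |
| `ontolabel.corpus` | documents, token sequences, spans, IO/BIO schemes, JSONL/CoNLL I/O |
| `ontolabel.ontology` | terminology ingestion/normalization, type distributions, coverage ranking, partitioning |
| `ontolabel.labeling` | LF templates (semantic-type, synset/Schwartz–Hearst, context-window cues, patterns), label matrix |
| `ontolabel.label_model` | majority vote, moments, triplet accuracies, posterior, predictions |
| `ontolabel.end_model` | noise-aware loss, abstain masking, hashed window encoder, training |
| `ontolabel.evaluation` | exact-span and micro token PRF, Wilcoxon comparison reports |
| `ontolabel.synthetic` | seeded worlds, corpora, noisy sources, raw vote matrices |
| `ontolabel.pipeline` / `ontolabel.cli` | config, end-to-end runner, partition sweep, CLI |

See `docs/methods.md` for modeling assumptions, defaults, and limitations.
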