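# Methods

## Problem setting

We treat entity classification as word-level sequence labeling: each
sentence X = (x₁, …, x_t) has a latent tag sequence Y with classes
y ∈ {0, …, k} (0 = outside/negative). No hand labels are available at
training time. Instead, m labeling functions (LFs) vote per word in
{−1, 0, …, k}, where −1 abstains. Two task shapes are supported: NER (tag
every word; binary per entity type, IO scheme) and span attribute
classification (negation, document-relative time), where entities are given
and only their head word — by convention the span's first token — is
classified.

## Labeling functions

**Semantic-type LFs.** One per terminology. Terms are normalized
(stopwords, pure numbers, and single-character terms dropped; tokens
lowercased except abbreviation-like tokens — ≤6 characters with ≥2
uppercase letters or all-caps — which keep case and match case-sensitively).
Matching is greedy leftmost-longest over normalized token tuples, which
disambiguates nested terms ("lung" as anatomy inside "lung cancer" as
disease). Each matched term is assigned the argmax of its class-probability
vector (normalized provenance counts of (terminology, term, class)
assignments, one count per source); exact argmax ties abstain. A slot
pattern `{*} ({*})` captures simple appositive mentions ("Tylenol
(Acetaminophen)") when both slots independently match same-class terms;
patterns beat equal-length plain matches, longer plain matches beat nested
patterns. Unmatched tokens abstain by default; `unmatched: negative`
(vote 0) suits guideline-style sources that assert non-entity-hood. Whether
a given deployment's ontologies should vote 0 on unknown words is genuinely
unsettled, so it is a per-LF switch with the conservative default.

**Synset LFs.** Document-scoped synonym sets: a synset fires only when ≥2
distinct member terms match in the same document, then labels every member
occurrence — the mechanism that disambiguates abbreviations whose long form
appears elsewhere in the note. Optional Schwartz–Hearst mode extracts
"long form (SF)" definitions by the standard right-to-left character
matching rule and links the short form as a temporary synset member, so
out-of-dictionary abbreviations inherit the long form's label.

**Context-window LFs** (span tasks): scan a token window left/right/either
of the target span for literal or regex triggers, first hit wins; plus a
nearest-datetime heuristic that parses explicit dates (ISO, MM/DD/YYYY,
"Month D, YYYY" — a deliberately bounded dialect set) and compares the
nearest one (token distance, within the window) to the document timestamp to
emit before/after/overlap. Missing timestamps make the rule abstain. Rule
*content* (cue lists) is data, supplied in config; the engine is the
contract.

**Pattern LFs.** Regex or small dictionaries with a fixed emitted class,
including class 0 (punctuation/stopword/number guideline dictionaries).
Invalid regexes fail at load time, not at labeling time.

## Label model

Assumptions: LF errors are conditionally independent given the true label,
with a symmetric class-conditional accuracy per LF per one-vs-rest class
view; abstention is independent of the true label (modeled separately as a
propensity).

Estimation: for each class c, votes binarize to +1 (voted c), −1 (voted
something else), 0 (abstained). Pairwise moments Mᵢⱼ = mean(λᵢλⱼ) are taken
over units where both LFs vote; pairs with <25 co-votes are flagged
unreliable and excluded. Accuracy magnitudes come from triplets,
|aᵢ| = √|Mᵢⱼ·Mᵢₖ/Mⱼₖ| (triplets with |Mⱼₖ| < 10⁻³ skipped), aggregated by
median; relative signs from sign(M) against the strongest LF; the global
sign is fixed by requiring mean accuracy > 0 (sources better than random on
average). Estimates are clamped to ±(1−ε), ε = 0.01. Optional refinement
(on by default) runs deterministic L-BFGS-B on
Σᵢ<ⱼ (aᵢaⱼ − Mᵢⱼ)² + λ‖a − a₀‖², λ = 0.05, initialized at the triplet
estimates and pulled toward the uniform accuracy prior a₀ (default 0.7 on
the probability scale; the prior's value is a tuning knob, not derived).
With refinement off, the fit equals the raw triplet estimates exactly.
Fewer than three usable LFs fall back to the prior with a warning.

Posterior: P(y|λ) ∝ prior(y) · Πᵢ f(λᵢ), with f = accᵢ(y) when λᵢ = y,
f = (1 − accᵢ(y))/(k′−1) for a disagreeing non-abstain vote (errors spread
uniformly over the k′−1 wrong classes, matching the symmetric-noise
assumption), and abstains contributing nothing. For binary tasks this is
identical to the one-vs-rest product form; for multiclass it is the direct
naive-Bayes factorization of the same assumption, and it is verified
exhaustively against brute-force enumeration of the generative model. The
class prior defaults to add-one-smoothed majority-vote frequencies.
Uncovered words get the prior; hard predictions break exact posterior ties
(and uncovered words) to the default class, mirroring majority vote's
tie/abstain policy. Dependency/correlation structure between sources is
deliberately not modeled.

## End model

A per-token softmax classifier over pluggable features minimizes the
noise-aware loss (expected cross-entropy under the label-model posterior),
with all-abstain tokens masked out of both the loss and the gradient.
Default encoder: sparse hashed indicators (CRC32 into 2¹⁵ buckets) of token
identity, lowercase form, character shape, 3/4-gram prefixes and suffixes,
and lowercase neighbors at ±1, ±2 — a deliberately lightweight encoder whose
role is to preserve the training semantics (soft labels + masking) while
letting the classifier generalize through sub-word and context features; a
`PrecomputedEncoder` hook accepts externally computed per-token embeddings
(e.g. from a contextual language model) without the package depending on
one. Optimization: mini-batch gradient descent (batch 64), learning rate 0.5
with 10% linear warmup then linear decay, L2 10⁻⁴, early stopping on
validation token F1 (patience 5) against the hard argmax of the soft labels
on a held-out document split (seeded hash of doc id, 10% by default). Token
F1 (not span F1) is the early-stopping criterion — a configurable choice.
Training is deterministic given the seed.

## Evaluation

NER: exact span matching — credit only for identical (sentence, start, end,
class) — computed after converting IO predictions to BIO so head-word errors
count. Span tasks: micro-averaged token PRF (pooled counts). F1 uses the
0/0 → 0 convention. Comparison reports give mean ± SD over seeded
replicates and two-sided Wilcoxon signed-rank p-values with Pratt
zero-handling (the variant is stated because it changes p under ties);
all-zero differences report p = 1 by convention, and fewer than 5 paired
replicates omit significance. No multiple-comparison correction is applied
across tasks. Scores are stored as proportions and reported ×100.

## Synthetic worlds

The generator emulates the statistical structure the method assumes, not
clinical language. Sentences are i.i.d. draws from a background vocabulary
(300 words built from one syllable inventory); with probability equal to the
entity density (default 0.5 per sentence) one lexicon term is inserted at a
random position and recorded as a gold span. The entity lexicon (default 60
terms per class) uses a disjoint syllable inventory plus class-specific
suffixes (-mab, -nib, -itis, …), mimicking the morphological regularity of
biomedical nomenclature; 30% of entries are 2–3 tokens to exercise
longest-match logic, and 20% get an abbreviation synonym for synset tests.
Sources are sampled with controlled recall (fraction of the lexicon known),
background coverage (fraction of background vocabulary correctly mapped to
class 0 — the analogue of an ontology's non-target semantic types), spurious
term inclusion, and type-assignment error. A calibration helper sizes the
spurious set from observed corpus token frequencies to hit a target
word-level precision, since precision is corpus-dependent. The raw
vote-matrix generator draws truth from a class balance and votes correctly
with per-LF probability, wrong classes uniform, abstaining independently —
exactly the independence structure the estimator assumes (verified by
near-zero within-class error correlations).

What passing these tests does *not* show: robustness to correlated source
errors (shared ancestry between real terminologies violates independence),
to context-dependent word senses (every synthetic token is unambiguous), to
realistic tokenization noise, or to distribution shift between training and
deployment notes. The generalization result in particular leans on the
engineered morphological regularity of entity tokens; real out-of-dictionary
generalization requires contextual representations via the encoder hook.

## Problem sizes and numerical choices

The shipped study harnesses use 400-sentence corpora for the mixed-quality
comparison (50 seeds), 600 sentences for end-model generalization (20
seeds), and m = 8, n = 10,000 for accuracy recovery (20 seeds) — sizes at
which the measured quantities are stable across seeds while the whole
reproduction script completes in well under a minute on one CPU. Tolerances:
moment reliability needs 25 co-votes; triplet denominators below 10⁻³ are
skipped; accuracies clamp at ε = 0.01; posterior normalization is done in
log space; predicted probabilities are clipped at 10⁻¹² inside the loss.
Degenerate inputs (empty matrices, <3 LFs, all-abstain rows, zero unmasked
training tokens, malformed BIO) either fall back with a logged warning or
raise with a named location, as documented per function.
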