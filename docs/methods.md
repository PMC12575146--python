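# Methods

`mbehrt` models longitudinal breast-cancer EHR trajectories with BERT-style
transformers and predicts 3-year disease-free survival (DFS) from two
modalities — structured visit data and free-text reports — fused by
cross-attention.  This note describes the model, its assumptions, the
defaults, the synthetic data generator, and the numerical choices.

## Clinical feature engineering

Each visit contributes at most 17 feature tokens:

* **Biological markers** (MONO, LEUK, LYMP, PN, CA 15-3; the panel is the set
  of markers with under 30% missingness): a binary token — `1` outside the
  marker's normal range, `2` inside — and a delta token,
  `round((v_t − v_{t−1}) / 10)`, emitted only when nonzero.  The normal range
  is treated as a closed interval: a value exactly on a boundary is normal.
* **Dynamic Nottingham Prognostic Index** (dNPI):
  `NPI = 0.2 × tumor size (cm) + grade + node stage`, with node stage 1/2/3
  for 0 / 1–3 / >3 involved nodes.  The NPI is recomputed whenever a new
  tumor size is measured (carried forward between measurements) and encoded
  as its Blamey prognostic-group token (EPG ≤ 2.4 < GPG ≤ 3.4 < MPG I ≤ 4.4
  < MPG II ≤ 5.4 < PPG ≤ 6.4 < VPPG).  Missing nodes impute to 0, grade to
  G2, and tumor size to the modal size among patients sharing the TNM stage;
  if no size can be obtained, the token is simply skipped.
* **Department, procedure, therapy, subtherapy** as categorical tokens
  (labels normalized by lowercasing, accent/punctuation stripping, synonym
  merging, and removal of labels seen fewer than 100 times corpus-wide).
* **Age** at visit, rounded to the nearest year, and the **molecular
  subtype** (static, repeated at every visit).

Missing features are skipped rather than imputed at the token level: the
parallel *modality* layer tells the encoder which feature type each token is,
so absent tokens carry no signal of their own.  Rounding is half-away-from-
zero throughout (ages, deltas); the choice is centralized in
`cohort.round_half_away`.

Trajectories are `CLS + visit tokens + SEP` per visit, with four aligned
layers (token, modality, delay bucket, 0-based position), truncated to the
**first 512** entries.  The delay layer buckets the gap to the previous
visit: W0–W3 cover [0, 28) days in 7-day weeks, M1–M12 cover [28, 365) as
`ceil(days/30)` clipped to 12, and LT is ≥ 365 days.  The month/week seam is
not uniquely determined by the bucket names alone; this tiling was chosen so
that every nonnegative gap maps to exactly one bucket, and is a convention of
this package.  CLS carries W0; each SEP carries its visit's bucket.

Cohort filters for the 3-year DFS task: history is windowed to [diagnosis −
182 days, first surgery + 365 days] (the upper end is the *index date*);
patients relapsing before the index date, censored before 3 years, or with
fewer than 3 visits are excluded, each with a single reason code.  Survivors
of the filter are labelled by event-within-1095-days.

## Trajectory encoder and MLM pretraining

The encoder is a pre-norm transformer whose input embedding is the sum of
four learned tables (token + modality + delay + position).  Reference
configuration: 5 layers, 12 heads, hidden 144, intermediate 133, max length
512, Adam at 1e-3, batch 64, 120 epochs.  Tests and desk-scale studies use a
2-layer/hidden-32 instance.

Pretraining corrupts each sequence position independently: MASK with
probability 0.15, swap to a uniformly random *different* content token with
probability 0.02 (disjoint events; CLS/SEP/PAD are never corrupted).
Per-position Bernoulli corruption (expected 15%/2%, not exact counts) keeps
batches independent.  Swapped positions carry prediction targets by default
(BERT convention); `swap_in_loss=False` restricts the loss to masked
positions.  The loss is cross-entropy at corrupted positions only, on a 90/10
train/validation split.  Embedding quality is summarized by *precision* —
top-1 accuracy at masked positions, computed with a fixed masking seed so the
metric is stable — and compared against a baseline trained on sequences whose
content (token, modality) pairs were shuffled within-sequence (the delay and
position layers stay put: they describe visit timing, not token identity).
For downstream use, the token-embedding tables of five differently-seeded
runs are standardized per dimension across the vocabulary and averaged.

The whole network stack (including Adam and backpropagation) runs on a small
NumPy reverse-mode autodiff core written for this package; with the model
sizes above it is single-core friendly and bit-reproducible, which the
determinism tests rely on.

## Classifiers

*Tabular*: the pretrained encoder with the MLM output layer replaced by a
single feed-forward layer + sigmoid on the CLS representation (reference
fine-tuning: lr 1e-4, batch 16, 5 epochs).  *Text*: reports are preprocessed
(lowercase, accents/punctuation stripped, stopwords removed), each token is
embedded by a pluggable embedder, and a report's embedding is the **sum** of
its token embeddings; the patient's chronological in-window report vectors
(diagnosis → index date), with learned CLS/SEP vectors and delay embeddings,
feed a second transformer and the same head (reference: lr 5e-4, batch 32,
99 epochs; d_text = 768).  The default embedder is a deterministic
hash-seeded unit-Gaussian stub: it carries no semantics, but preserves
bag-of-words geometry (a planted phrase shifts the report sum by a fixed
vector), which is exactly what the synthetic studies need.  Because events
are rare, every classifier trains on class-balanced batches: half positives,
half negatives, majority class without replacement per epoch, minority with
replacement.

*Fusion*: the text model's CLS representation, projected to the tabular
width (reference 768 → 144), is the attention query; the tabular encoder's
hidden sequence provides keys and values (PAD masked).  The classifier head
receives the attention output concatenated with the query and the tabular
CLS representation — residual paths that let the fused model always fall
back on either submodel.  A published description of this fusion reads "the
logits" as the vectors entering the heads; a literal scalar-logit mode is
available (`logit_mode="scalar"`) but is degenerate as attention (a single
key) and is off by default.  Both submodels are frozen during fusion
training — their outputs are precomputed constants, so their weights are
bit-identical before and after (asserted by hash in the tests); joint
fine-tuning is deliberately not supported.

## Interpretation

Integrated gradients along the straight path from an all-PAD embedding
baseline, midpoint Riemann rule; per-position scores are sums over embedding
dimensions, and the completeness gap |ΣIG − (F(x) − F(x'))| is always
reported.  The baseline choice (all-PAD) is a package convention and is
configurable.  For the text model, attribution runs over the assembled
CLS/report/SEP sequence against a zero-report baseline; a report's score is
the attribution at its own position.

Reports with attribution above the 95th percentile (per direction; the
threshold value is a package convention) form the DFS−- and DFS+-predictive
sets.  The phrase miner counts word n-grams (n = 3…9) by *document
frequency* (reports containing the phrase), takes each group's top 30 (ties
broken lexicographically), returns the DFS−-only phrases, and merges phrases
that are contiguous sub-phrases of a longer retained phrase.  Extracted
phrases are validated by splitting the cohort on phrase presence and
comparing Kaplan–Meier DFS curves with a two-group log-rank test (both
hand-implemented from the product-limit / observed-vs-expected formulas;
the test suite checks them against an independent survival library).

## Evaluation

AUC-ROC with a class-stratified percentile bootstrap CI (2000 resamples
default; percentile rather than BCa for simplicity), average precision (used
as the model-selection criterion), DeLong's paired test via placement
values, an NPI-at-diagnosis clinical baseline, and per-stratum reports that
refuse to score strata with fewer than 5 members of either class.

## Synthetic cohort generator

`simulate.generate_cohort` emulates the data structure the pipeline assumes:
per-patient demographics and tumor features; visit processes over the
[−6 months, +1 year] window; departments drawn jointly with a department-
specific procedure list (so the MLM has co-occurrence structure to learn);
five markers with configurable per-visit missingness; templated pseudo-French
reports with optional multi-word signal phrases injected into relapse-bound
patients' reports.  The event model is logistic in (NPI, molecular subtype,
ever-abnormal CA 15-3) with the intercept calibrated by bisection to a
target prevalence (default 6.2%); event times are exponential with the rate
matched to that probability at the 3-year horizon, giving both a binary
label and KM-compatible times.  Censoring is independent of covariates.
Defaults: 1.5 visits/month, mean report length 159 words, 20% marker
missingness, moderate positive effects for NPI/TNBC/abnormal CA 15-3 —
values a cohort of this kind would plausibly show; they are fixed, not
fitted.

What the generator does *not* emulate: real clinical language (templates are
structured pseudo-text), visit-pattern feedback (sicker patients do not visit
more often), informative censoring, or label noise.  Passing tests therefore
demonstrate that the machinery recovers signal it was designed to recover,
not clinical performance on real data; headline metrics from any real-cohort
study are out of scope here.

## Problem sizes and known limitations

The test and acceptance studies run at desk scale by design: cohorts of
250–450 patients, ~0.25–0.5 visits/month (sequences of ~40–100 tokens),
2-layer/hidden-32 encoders, and elevated prevalence (25–35%) with strong
planted effects in the parameter-recovery fixtures so that held-out splits
of ~100 patients retain enough events for bootstrap CIs.  Qualitative
properties (original > shuffled MLM precision, CIs excluding 0.5 for planted
signal and covering 0.5 for permuted labels, fusion ≥ best submodel under
complementary signals, dNPI-top attributions, phrase recovery) are asserted
at these scales.

Known limitations:

* MLM pretraining does **not** reliably improve small-sample fine-tuning on
  these synthetic cohorts: the label signal (a single prognostic-group
  token) is learnable from scratch, while the MLM learns label-irrelevant
  co-occurrence.  The learning-curve harness (`evaluate.pretraining_advantage`)
  is provided and tested for mechanics, but no directional claim is asserted;
  demonstrating a few-shot pretraining benefit needs data where context
  carries label-relevant structure.
* The hash-stub embedder ignores morphology and synonymy; plug a real
  clinical-language embedder into `TokenEmbedder` for semantic studies.
* The fusion attention is single-head by default; head count and the
  query/key role (text→query by default) are configurable.
* Divergence (NaN loss) aborts training with diagnostics rather than
  attempting recovery; learning rates above ~3e-3 on the tiny configs can
  trigger this.
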