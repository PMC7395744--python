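# Methods

This note documents the models, algorithms, and design choices behind
`earlywarn`: what is computed, under which assumptions, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

The package predicts three forms of acute critical illness — sepsis, acute
kidney injury (AKI), and acute lung injury (ALI) — from routinely collected
EHR event streams, and explains every prediction by attributing it back to
the input observations.  An admission is a time-ordered sequence of events
(timestamp, parameter, value) over 33 clinical parameters: 27 laboratory
analytes and 6 vital signs.  A model consumes a 24-hour retrospective
observation window ending at the prediction time and emits the probability
that the illness develops; models are trained and evaluated at lead times
(horizons) of 0, 3, 6, 12, and 24 hours before onset.

## Data model and preprocessing

**Hourly binning.**  The observation window is divided into 24 one-hour bins;
all observations of a parameter inside a bin are averaged.  Bins are
half-open intervals `(start, end]` whose last bin ends exactly at the
prediction time, which guarantees causality at the boundary: an event
time-stamped after the prediction time can never enter the window.

**Imputation.**  Cells with no observation are carried forward from the most
recent earlier bin in the window; cells before the first observation take the
per-parameter median of the training population.  The observation mask is
kept alongside the imputed values.  An alternative design — feeding the mask
to the network as extra channels — was considered and not implemented; the
carry-forward convention mirrors what the score-based baselines use.

**Standardization.**  After imputation each parameter is z-scored with
training-fold mean and standard deviation, then winsorized at ±5 standard
deviations.  Several laboratory analytes (CRP, prolactin, lactate,
sedimentation rate …) are heavily right-skewed; without winsorization a
single extreme draw, made persistent by carry-forward, can dominate a window
by tens of standard deviations.  All preprocessing statistics are fitted on
training folds only and serialized with the model, so no test statistics leak
into preprocessing.

**Admission bounds.**  The events CSV carries only the five event columns, so
admission bounds are inferred from the event span: admission start is the
first vital-sign observation (vitals are recorded from arrival; laboratory
history may legitimately precede admission), discharge is the last event.

## Gold-standard outcome labeling

* **Sepsis** follows the Sepsis-3 consensus.  Suspected infection (SI) is the
  earliest qualifying culture/antibiotic pair: antibiotic within 72 h after a
  culture, or culture within 24 h after an antibiotic; the SI time is the
  earlier event of the pair.  Organ dysfunction is an acute SOFA increase of
  ≥ 2 points inside the window from 48 h before to 24 h after SI, measured on
  hourly carry-forward snapshots as the maximum over the window of the score
  minus its running minimum (a rise of two points after its own baseline).
  Onset is anchored at the SI time.  The SOFA implementation scores the
  subsystems representable with the 33 parameters — coagulation (platelets),
  liver (bilirubin), cardiovascular (mean arterial pressure from
  systolic/diastolic), renal (creatinine), and a capped SpO₂ proxy for
  respiration (no FiO₂ is recorded); CNS, urine output, and vasopressor
  subsystems score 0.
* **AKI** uses the two creatinine KDIGO definitions, collapsed to a binary
  label: a rise of ≥ 26.5 µmol/l over the minimum of the preceding 48 h, or a
  value ≥ 1.5× the habitual level, computed as the mean over the preceding
  365 days (pre-admission history counts; with no history the habitual level
  is undefined and the criterion cannot fire — no history is fabricated).
  Onset is the earliest firing measurement.  The urine-output criterion needs
  data outside the parameter set and is out of scope.
* **ALI** is operationalized as the first CPAP or NIV event.

All threshold comparisons are inclusive (≥), applied uniformly.  The labelers
are verified against independent brute-force oracles (exhaustive scans over
all event pairs and snapshot pairs) on 1000 generated admissions.

## Synthetic cohort generator

The restricted study cohort is emulated by a generator whose defaults encode
the published cohort structure: outcome prevalences 2.44% / 0.75% / 1.68%
(sepsis / AKI / ALI), median length of stay 153.6 h (log-normal, σ = 0.6 on
the log scale, clipped to 2–30 days), and ≈ 39 laboratory measurements per
admission at the reference stay, allocated across analytes by clinically
weighted Poisson counts (frequent chemistry/haematology panels, rare blood
gases) and scaled with the length of stay.  Vitals are observed every 2–8 h.

**Value model.**  Each parameter carries per-outcome 5th/50th/95th percentile
triples for positive and negative admissions.  Values are drawn from a
two-piece split-normal defined by quantile splicing — `Q(u) = m + s_lo·z(u)`
below the median and `m + s_hi·z(u)` above, on a log scale for skewed
positive analytes — which reproduces all three percentiles exactly.  Each
admission draws a baseline percentile `u₀ ~ U(0.02, 0.98)` and jitters it
(σ = 0.08 in percentile space) per observation, giving within-admission
variation much smaller than population variation, as in real data.

**Deterioration drift.**  Positive admissions sample from the outcome-negative
profile far from onset and interpolate linearly, in quantile-parameter space,
to the outcome-positive profile over the final 24 h before the planted onset
(optionally restricted to chosen parameters and scaled by a drift factor).
This creates the "recent values matter" structure that the explanation module
is expected to recover.

**Label consistency by construction.**  Each positive admission emits exactly
the events its labeler needs, with controlled trajectories so the labeler
recovers the planted onset: sepsis admissions plant a culture/antibiotic pair
at onset plus a platelet drop from a high plateau to 60–90 ×10⁹/l (a
coagulation-subscore rise of exactly 2); AKI admissions plant a creatinine
ramp whose first crossing of the +26.5 µmol/l threshold is the onset
measurement, with optional pre-admission history for the habitual baseline;
ALI admissions plant a CPAP event at onset.  Conversely, creatinine in
non-AKI admissions follows a smooth baseline (±4% multiplicative noise)
because the KDIGO criterion keys on absolute 48-h excursions — independent
percentile resampling would plant spurious kidney injuries.  Negative
admissions emit no marker events and therefore label negative by
construction.

**Determinism.**  All randomness flows from one master seed through
per-admission seed sequences; the same specification reproduces event files
byte for byte.

**What the generator does not model:** inter-parameter correlation beyond the
class-conditional drift, demographics, multi-admission patients, measurement
batching beyond per-analyte rates, and informative missingness.  Passing the
synthetic benchmarks therefore demonstrates that the pipeline recovers the
structure the generator plants — not clinical-grade performance on real
records.

## Prediction network

A temporal convolutional network operating on the 24×33 standardized window:
three temporal blocks, each `[causal dilated conv → ReLU → spatial dropout →
normalization → causal conv (dilation 1) → ReLU → spatial dropout →
normalization]`, with 64 filters, kernel size 4, and first-convolution
dilations 1, 2, 4 across the blocks; then global average pooling over time, a
bias-free dense projection to two classes, and a softmax.  The receptive
field is `1 + Σᵢ (k−1)(2^(i−1)+1)` = 31 time steps for kernel 4 and three
blocks, checked empirically by perturbation probes.

**Every linear map is bias-free.**  This is a hard contract: with only ReLU
non-linearities and no additive terms, the logits are positively homogeneous
in the input (`f(cx) = c·f(x)`, zero input ⇒ zero logits), which underpins the
explanation module's conservation and equivalence guarantees.

**Normalization.**  The normalization layers are parameter-free per-channel
RMS scalings.  During training the batch RMS is used (with gradients taken
through the statistic) and a running RMS is tracked; at inference the running
RMS is a recorded constant, so the layer is an exact bias-free diagonal
linear map and all homogeneity/causality properties hold exactly.  A
learnable shift (as in standard layer normalization) would introduce a bias
and break the explanation contract, so none is used.

**Training.**  Cross-entropy with Adam (learning rate 10⁻³), mini-batches of
200, dropout 10%, He-normal initialization, early stopping on validation loss
(patience 5 by default) with best-validation weights restored.  Optional
extras, all off by default: positive-class oversampling with replacement,
plateau learning-rate decay, a minimum-epoch warmup before early stopping
may fire, decoupled weight decay, Gaussian input-noise augmentation,
per-sample input-channel dropout (bagging over parameter subsets, which
curbs reliance on spurious channels when cohorts are small), an AUROC-based
early-stopping monitor (appropriate when the end metric is ranking),
Polyak/EMA weight averaging (averaged weights remain bias-free, so the
explanation contracts are unaffected), and probability averaging over
independently initialized networks (`n_ensemble`).  The defaults correspond
to the large-cohort setting; the synthetic benchmarks in the test suite (two
to three orders of magnitude fewer admissions) use batch 32, patience 20,
plateau decay ×0.5, input noise σ = 0.6 on the standardized inputs,
input-channel dropout 0.4, the AUROC monitor and a 2-member ensemble —
small-sample regularization and variance reduction around the same model,
not changes to the architecture.  On the planted-signal benchmark the
channel dropout alone was worth ≈ 0.03 AUROC: with 33 channels, 1600
training windows and one informative channel, the unregularized network
overfits the nuisance channels.

**Sample construction.**  One window per admission per horizon: positives are
anchored `horizon` hours before onset (skipped when less than a full 24-h
history exists); negatives at a seeded uniform-random time between
admission + 24 h and discharge.  How the original study anchored control
windows is not stated anywhere; uniform anchoring is this package's choice.

## Explanation module

Relevance propagation anchors at the pre-softmax logit of the explained class
(the softmax itself receives no rule) and redistributes it backward:

* **z-rule (LRP-0):** `R_{i←j} = w_ij a_i / Σ_i w_ij a_i · R_j` — used as the
  all-layer composite for the Gradient×Input equivalence.
* **z⁺-rule (LRP-α₁β₀):** the same with `w⁺ = max(w, 0)` — used for all
  intermediate layers (convolutions, dense head, and global average pooling
  treated as a linear layer with uniform weights 1/T), producing sparse
  one-signed explanations.
* **w²-rule:** `R_{i←j} = w_ij² / Σ_i w_ij² · R_j` at the input-adjacent
  convolution, appropriate for real-valued (standardized) inputs.  The
  denominator counts only real input positions, never the causal zero
  padding, so no relevance is absorbed at the window boundary.

ReLU and dropout layers pass relevance through (a dead unit's activation is
zero, so it receives zero relevance from above); normalization layers are
constant per-channel scalings at explanation time and cancel inside the
rules.  Near-zero denominators are stabilized by a sign-matched ε = 10⁻⁹;
because the network is bias-free, a zero denominator implies a zero-relevance
neuron, so the stabilizer's absorption is bounded by ε-level noise.  Total
input relevance equals the anchored logit (conservation, verified to 10⁻⁴
relative over random networks), and because Σ relevance equals the logit, a
more confident prediction distributes proportionally more relevance.

On this architecture the all-z-rule composite coincides with Gradient×Input
(elementwise product of the logit gradient with the input, zero baseline);
the package computes both by different code paths and the test suite verifies
their agreement to 10⁻⁵, making Gradient×Input the independent oracle for the
propagation code.

**Aggregation.**  Population-level importance is computed over positively
labeled admissions only: the per-parameter mean relevance across all time
steps and patients (temporal variation deliberately ignored, every data point
weighted equally, no per-patient renormalization), sorted descending; the
local-explanation summary keeps the flattened (relevance, value) cloud with
values colored by their position between cohort-wide 5th/95th percentile
anchors.  Per-patient exports keep the 10 highest-ranking parameters by mean
relevance.

## Baselines

* **MEWS** — the ward early-warning score used directly as a risk ranking,
  recomputed at prediction time from carry-forward vitals.  The Danish
  variant's banding tables are not published; the standard bands are used,
  extended with a pulse-oximetry band, and can be overridden.
* **SOFA** — the same construction over the SOFA score.
* **GB-Vital** — a gradient-boosted tree classifier (300 trees, depth 3,
  learning rate 0.1 — conventional defaults, recorded in the model object)
  over 30 features: for each of the six vitals, the hourly means of the
  current, prior, and second-prior hours plus the two trends between
  succeeding means (sign convention: later minus earlier).

## Evaluation

Five-fold patient-level cross-validation: patients are shuffled once into
five portions; each rotation trains on four portions and splits the held-out
portion in half into validation (early stopping) and test, so every patient's
windows stay on one side of every split.  Discrimination is measured by AUROC
(Mann–Whitney, ties counted ½ — required for the integer-scored baselines)
and AUPRC (step-wise average precision rather than trapezoidal interpolation,
which is optimistic in PR space).  Summaries report the per-horizon mean with
a normal-approximation 95% CI, mean ± 1.96·sd/√5, across fold values; a
percentile CI across five values would be degenerate.

## Numerical and degenerate-input conventions

* Degenerate percentile triples (p5 = p95) become point-mass samplers with a
  warning.
* All-missing score snapshots warn and score 0.
* Single-class training sets and single-class metric inputs raise errors.
* The ε stabilizer is sign-matched; absorbed relevance is bounded as argued
  above.
* Random draws use `numpy` Generators seeded from explicit seeds everywhere;
  per-admission and per-fold seeds derive deterministically from master
  seeds.

## Benchmark design and problem sizes

The planted-signal benchmark generates 2000 admissions with ALI prevalence
0.25, with the deterioration drift restricted to the pulse rate at twice the
profile shift (a single strongly informative channel).  ALI is the right
outcome for this benchmark because its labeler marker (CPAP) is not among the
33 model channels, so the drift channel is the only model-visible signal.
The enriched prevalence gives stable fold-level metrics at this cohort size;
the study prevalences remain the generator defaults used everywhere else.
The test asserts five-fold mean AUROC ≥ 0.85 at horizon 0 and that the pulse
rate ranks first in global mean relevance.  Other tests use cohorts of 80 to
1000 admissions.  For comparison, a logistic model given only the pulse
channel reaches ≈ 0.94 AUROC on this benchmark, so the bar tests signal
recovery, not the ceiling.

## Known limitations

* The SOFA respiration proxy and the MEWS SpO₂ band are package conventions,
  not published tables.
* The synthetic learnability results say nothing about real-cohort
  performance; the published cohort is access-restricted.
* The AKI habitual-creatinine baseline uses all strictly earlier measurements
  in the 365-day window, including in-admission values.
* Relevance through the normalization layers treats the recorded scale as
  constant; how the original system handled its normalization layers is not
  described, and this is an interpretation.
* Global importance is pooled without per-patient normalization; patients
  with higher logits contribute proportionally more relevance.
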