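# earlywarn

Explainable early-warning models for acute critical illness — sepsis, acute
kidney injury (AKI), and acute lung injury (ALI) — from EHR event streams.

Ward early-warning scores (MEWS, SOFA) weigh a handful of vitals with fixed
points tables; deep models predict deterioration earlier and more accurately
but are opaque, which blocks clinical adoption.  This package implements the
full pipeline of an *explainable* alternative for researchers working with
admission-level EHR time series: a temporal convolutional network (TCN) that
predicts illness onset from a 24-hour observation window, paired with a
relevance-propagation explanation module that attributes every prediction
back to the specific clinical parameters and hours that drove it — plus the
gold-standard outcome labelers, score-based baselines, a synthetic cohort
generator, and a cross-validated evaluation harness.

## The model

Each admission is a time-ordered event stream over 33 clinical parameters
(27 laboratory analytes, 6 vital signs).  The observation window ending at
prediction time *t* is binned into 24 one-hour means **x** ∈ ℝ^{24×33}
(half-open bins, last bin ending exactly at *t*), carry-forward imputed,
z-scored with training-fold statistics, and fed to a TCN: three temporal
blocks of dilated causal 1-D convolutions (64 filters, kernel *k* = 4,
dilations 1/2/4, each block's second convolution at dilation 1, ReLU, spatial
dropout, parameter-free RMS normalization), global average pooling over time,
and a bias-free dense softmax head.  The receptive field is

    1 + Σ_{i=1..n} (k − 1)(2^{i−1} + 1)  =  31 hours   (k = 4, n = 3 blocks).

Because the network contains only ReLUs and bias-free linear maps, its logits
are positively homogeneous in the input, and the prediction f_c(**x**) can be
decomposed exactly onto the input grid by layer-wise relevance propagation
(deep Taylor decomposition): the z⁺-rule

    R_{i←j} = w⁺_ij a_i / Σ_i w⁺_ij a_i · R_j

through all intermediate layers and the w²-rule at the input layer, anchored
at the pre-softmax logit.  The resulting 24×33 relevance map conserves the
logit (Σ R = f_c) and, with the plain z-rule everywhere, equals
Gradient × Input exactly — a property the test suite verifies numerically.

Outcome labels follow the published gold standards: Sepsis-3 (suspected
infection from culture/antibiotic co-occurrence windows plus an acute SOFA
rise ≥ 2), the creatinine KDIGO criteria for AKI (+26.5 µmol/l within 48 h,
or ≥ 1.5× the 365-day habitual level), and first CPAP/NIV use for ALI.

## Worked example

The study cohort behind the original system is access-restricted, so the
package ships a generator that emulates its structure (per-outcome percentile
profiles, event sparsity, admission lengths, outcome prevalences).  The
whole pipeline runs from the `earlywarn` command:

```bash
earlywarn simulate --n 1000 --seed 7 --out events.csv --labels planted.csv \
    --ali-prevalence 0.25
earlywarn label --events events.csv --out labeled.csv
printf 'train:\n  batch_size: 32\n  max_epochs: 60\n  patience: 12\n  lr_decay: 0.5\n' > cfg.yaml
earlywarn train --events events.csv --labels planted.csv --illness ali \
    --horizon 0 --config cfg.yaml --seed 2 --out model/
earlywarn explain --model model/ --events events.csv --admission adm-00002 \
    --prediction-time 2016-01-05T07:18:00 --out relevance.csv
```

which prints (numbers from this exact seeded run):

```
wrote 278695 events for 1000 admissions to events.csv
labeled 1000 admissions -> labeled.csv
trained 29 epochs on 900 samples -> model/
p(positive) = 0.997; logit relevance total = 2.7306 -> relevance.csv
```

`labeled.csv` reproduces the planted outcomes exactly — for every admission
and every illness, the gold-standard labelers agree with the generator's
planted ground truth, onsets included.  The training command fits one
illness/horizon model with early stopping (the config file adapts the batch
size and patience to this small cohort; the defaults suit large ones) and
writes the weights plus the fitted preprocessing state.  The explain command
emits a long-format CSV (hour, parameter, value, relevance) for one
admission at its onset — a true ALI case predicted positive with probability
0.997.  The relevance total equals the explained logit, and averaging the
map per parameter ranks the deteriorating channels first: sedimentation
rate (0.0049), SpO₂ (0.0047), potassium, neutrophils, CRP — all parameters
whose profiles the generator shifts before ALI onset.
`earlywarn explain-cohort` aggregates such maps over all positive admissions
into a global parameter-importance ranking, and
`earlywarn evaluate --models tcn,mews,sofa,gb-vital` cross-validates any of
the models over the 0/3/6/12/24-hour horizons with AUROC/AUPRC and 95% CIs.

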