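# Methods

## The prediction problem

A patient with Alzheimer's disease (AD) is observed as a date-ordered stream
of coded encounters. At an *index date* — any encounter on or after the first
AD diagnosis — the model receives the preceding year of diagnoses (3-character
ICD-10 groups), drugs and abnormal lab flags, and predicts whether a psychosis
code will be recorded within the following 90 days. "3 months" is a single
constant (90 days) everywhere and is configurable.

Cohort rules, in order:

- a psychosis code recorded on the same calendar day as a delirium code is
  discarded (day-level resolution is all the event table carries, so
  "co-occurring" means same day);
- eligibility requires an AD diagnosis, at least `min_history_days` (365) of
  record before it, and no surviving psychosis code within `washout_days`
  (365) before AD onset. Psychosis older than the washout is tolerated by
  default; a strict variant (`strict_washout`) rejects any prior psychosis;
- an encounter is a *case* index if the first post-AD psychosis falls within
  (index, index + 90 d]; patients who never convert contribute a *control*
  index. Patients who convert later than the horizon are neither: treating a
  converter's early encounters as controls would label the same trajectory
  both ways;
- every qualifying pre-onset encounter of a case patient becomes a sample
  (augmentation); each control patient contributes only the latest qualifying
  encounter (latest-status reading). Controls are then undersampled uniformly
  at random (seeded) to a 1:1 ratio whenever enough exist;
- splits (8:1:1) are by patient, not by sample, so augmented samples of one
  patient never straddle folds — any other choice leaks outcome information
  into validation/test AUROC.

## Models

`LSTMRiskClassifier` embeds each token (dimension 128 by default), sum-pools
tokens within a visit, runs the visit vectors through a stacked LSTM (hidden
size 128, 2 layers, inter-layer dropout 0.2 by default) and maps the final
hidden state to an event probability. Training is binary cross-entropy with
Adam (learning rate 1e-3, batch 64 by default), at most `max_epochs` epochs,
stopping when validation AUROC has not improved for `patience` (3)
consecutive epochs and restoring the best-validation weights. The LSTM is
implemented directly in numpy (forward, full backpropagation through time,
Adam); the analytic gradients are validated against central finite
differences in the test suite. Token id 0 is padding and its embedding row is
pinned at zero, which makes "mask an occurrence to padding" and "delete the
occurrence" identical under sum pooling — the identity the occlusion
attribution relies on. Visit order is the only temporal information the model
receives; gaps between visits are not encoded.

`BagOfCodesLogisticClassifier` is the comparison model: one binary feature
per token (presence anywhere in the lookback window), ridge-penalized
logistic regression, inverse regularization chosen on validation AUROC from a
fixed grid (0.01, 0.1, 1, 10). It sees *whether* a code occurred, never
*when*.

AUROC is computed in the Mann–Whitney form (ties count one half) and agrees
with an all-pairs brute force by property test. `repeat_evaluate` re-trains
with seeds `base_seed + 0..n-1` on fixed folds and reports the mean and
sample standard deviation over 10 repeats by default.

## Attribution and the RC statistic

The contribution of feature *f* to one patient (FC) is the sum over
occurrences of *f* in the lookback window of
`risk(original) − risk(that occurrence masked to padding)`; a feature absent
from the window has FC = 0. Per patient the FC vector is normalized by the
total absolute contribution, `FC_f / Σ_g |FC_g|` (the absolute-value
denominator keeps mixed-sign vectors stable; an all-zero vector passes
through with a warning).

The relative contribution of *f* is the ratio of the arithmetic mean
normalized FC over **all** event samples to that over all non-event samples.
Including non-carriers (at FC = 0) matters: the group means then carry the
exposure-prevalence contrast as well as the per-carrier contribution, which
is where most of the recoverable signal lives at moderate sample sizes. A
protective feature has negative FC in both groups (masking it raises the
predicted risk); the ratio of two negative means is positive, and RC < 1
then means the feature moves predictions more for non-event patients. RC is
undefined — the row is excluded with a reason — only when the two group
means have opposite signs or either is zero.

Inference on the log scale uses the delta-method variance
`(sd_e/mean_e)²/n_e + (sd_c/mean_c)²/n_c` (sample standard deviations), the
log-normal interval `exp(ln RC ± 1.96 √Var)` — whose bounds satisfy
`√(lo·hi) = RC` exactly — and a two-sided z-test of `ln RC = 0`. Both
Benjamini–Hochberg (default, matching the report's FDR-adjusted Q values)
and Bonferroni corrections are available.

**Cross-fitting.** Contributions computed with a model on its own training
samples are anticonservative: the model partially memorizes chance
case/control prevalence imbalances, and the occlusion faithfully reports
that memorization as signal. Measured on null cohorts (no planted effects,
20 seeded replicates, Bonferroni), same-sample attribution produced a 9.3%
false-positive rate against the nominal 5%; attribution restricted to
held-out folds was calibrated (2.3%) but, at a fifth of the samples, too
weak to recover planted effects reliably. The default is therefore two-fold
cross-fitting by patient: each half of the cohort is attributed by a model
trained (with an internal patient-level early-stopping split) on the other
half. This is calibrated (1.8% null FPR) at full sample size.

**Anchor scaling.** Per-patient normalization makes every feature's share
depend on the patient's total contribution budget, which differs between
event and non-event groups; the RC of the AD diagnosis — carried by every
patient and, in the simulator, coded independently of the outcome — measures
that drift. After the table is computed, every RC and interval bound is
multiplied by `1/RC(anchor)` so the anchor sits at exactly 1. Scaling is a
rank-preserving recalibration of magnitudes; p and q keep their values from
the unscaled ratios (the direct test of "contributes more to cases"), so a
scaled interval can straddle 1 for a row whose unscaled ratio is
significant. `scale_to_anchor(..., recompute_significance=True)` instead
re-tests against the scaled null. The significant-features report drops the
anchor row itself and applies the reporting filter: q < 0.05, and for
diagnoses a population prevalence above 10%.

## The synthetic-data generator

`generate_cohort` emulates the statistical structure the analysis assumes,
not any real hospital's coding behavior. Per patient: encounter dates are
uniform over `years_followup` (8 y) at a Poisson rate (10/y), always
including day 0 and the AD onset day (uniform in days 400–800, guaranteeing
the 1-year history requirement); each background code (30 diagnoses, 20
drugs, 10 labs) gets a per-cohort carrier probability in 0.05–0.5 and
per-encounter recording probability in 0.1–0.4, giving a frequency spectrum;
planted codes use a common carrier probability (0.30) and recording
probability (0.25); lab results carry a categorical flag
(ABNORMAL/HIGH/LOW/NORMAL at 0.15/0.15/0.15/0.55) — only the flag exists, no
numeric value. The AD code repeats at 70% of post-AD encounters (chronic
re-coding), so it appears in every lookback window — the property the anchor
calibration needs.

After AD onset, consecutive 90-day windows draw a Bernoulli event with
probability `logit⁻¹(logit(p₀) + Σ log RR_f · w_f)`; `p₀ = 0.01` per window
(≈ 25–35% eventual conversion over the follow-up, leaving enough control
patients to balance the augmented case samples 1:1). Recency weights
`w = 0.5^(Δt/h)` default to a 180-day half-life, so *when* a code last
occurred carries signal beyond whether it occurred — the structure that
gives the sequence model its edge over the bag-of-codes baseline; `h = ∞`
disables decay. A psychosis event creates a same-day encounter; with
probability 0.05 a delirium code co-occurs (exercising the exclusion rule),
and 5% of patients carry a pre-AD psychosis code (exercising the washout).

The default benchmark profile plants two focal codes — a hazardous diagnosis
at RR 2.5 and a protective drug at RR 0.4 — plus seven accessory factors of
moderate strength across all three code types. A cohort with only the two
focal codes caps validation AUROC near 0.65, well below the predictability
regime the attribution method assumes, and was measured to starve the RC
statistic of signal; the multi-factor profile is the realistic condition.
The separate recency benchmark (`recency_benchmark_config`) plants a single
hazardous diagnosis carried by *every* patient (presence in a 1-year window
is near-certain for cases and controls alike) with a 60-day half-life: the
logistic baseline is blind by construction (validation AUROC ≈ 0.51) while
the sequence model reaches ≈ 0.56–0.65.

What passing tests do **not** show: the generator has no real ICD frequency
spectrum, no co-prescription or comorbidity correlation structure, no coding
idiosyncrasies, no informative-visit process (visit timing is independent of
health state), and demographics are emitted but not fed to the model.
Recovery of planted effects here demonstrates the pipeline's statistical
machinery, not performance on real EMR data.

## Problem sizes and numerical choices

Benchmark runs use a 32-unit single-layer LSTM (learning rate 5e-3, ≤ 30
epochs, patience 5): the synthetic vocabularies hold under a hundred codes,
so this is already past the data's capacity ceiling, and it keeps the full
recovery study (10 seeds × n = 2000 patients ≈ 2 700 samples each) and the
null study (20 replicates × n = 500) inside a few CPU-minutes. The paper-
scale defaults (128/128, 2 layers) remain the package defaults for real use.
Determinism: every stochastic step (simulation, undersampling, splits,
weight init, batch order, dropout) flows from explicit integer seeds through
`numpy.random.default_rng`; re-running any stage with the same config
reproduces identical artifact bytes. Probabilities from the hazard are
clamped to the open unit interval; BCE clips probabilities at 1e-12;
degenerate inputs (single-class folds, empty visit sequences, tokens outside
the vocabulary, non-finite contributions) raise immediately.

## Known limitations

- The occlusion masks one occurrence at a time; joint effects of co-occurring
  codes are attributed marginally, and strongly correlated features split
  their contribution in a model-dependent way.
- The z-test treats per-sample normalized FC values as independent
  observations; augmented samples of one patient violate this mildly.
- Anchor scaling assumes the anchor's true RC is 1; in data where AD coding
  frequency itself tracks proximity to psychosis, the calibration would be
  biased.
- The empirical relative-risk oracle dichotomizes exposure at the window
  level (ever-exposed before window start), leaving a small systematic
  offset from the planted odds-scale effect; its convergence test therefore
  checks narrowing bands rather than convergence to zero error.
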