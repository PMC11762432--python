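# Methods

## Cohort design and tensorization

The package models a dynamic cohort observed over a fixed study window
(default 2010-01-01 to 2019-12-31). A patient's entry date is the latest of
the study start, their 65th birthday, and their registry entry (arrival)
date; follow-up ends at death, registry exit, or the study end. Exclusions,
applied in order and counted: no recorded events; no primary-care visit in
the window; age ≥ 100 years at the study start; follow-up shorter than
`prediction_window + 1` years (the window must be ascertainable and at least
one history year must remain). A censored patient's partial final calendar
year is dropped — outcomes in a partly-observed year cannot be ascertained,
and keeping deaths while dropping censored survivors would bias outcome
rates upward (this was observed and fixed during development of the
generator/labeling contract).

Cleaning removes duplicate diagnoses (same patient, day and code), events
dated before birth or after death, and sex-specific diagnosis codes recorded
on the wrong sex (configurable code list; two defaults are built into the
synthetic schema).

Events are aggregated per calendar year (Jan 1–Dec 31) into 246 dynamic
variables in eight families: 60 chronic-disease occurrence flags and 37
frailty deficits (binary, once-present-always-present carry-forward —
chronicity implies persistence, including from records predating cohort
entry); 67 laboratory variables (21 analytes × test count / yearly mean /
out-of-reference-range count, plus 2 analytes without a reference range);
50 clinical measurements (16 numeric × count/mean, 9 categorical ×
count/mode, ties to the smallest category); 8 consultation counts; 9
admission counts; 3 billed-drug counts (ATC level-1 groups); 12 specific
acute-event counts. Two static variables (sex, socioeconomic quintile;
missing quintile encoded 0) complete the 248. Variable names are synthetic
(family prefix + index): the schema reproduces counts and aggregation
semantics, not a clinical code list, which is not in the public record.

The per-patient prediction index is the last observed year minus the
window, maximizing usable history; histories are **right-aligned** into the
`[n × T_max × V]` tensor (most recent year at the last slot) so "years
before the prediction" is a fixed index across patients. Two masks
accompany the values: the period mask (real year vs zero-padding) and the
value mask (recorded vs unrecorded within a real year). Counts,
out-of-range counts and carry-forward flags are *known-zero* in any
observed year (mask 1); means and modes are unknown when nothing was
measured (mask 0). No event dated after the index year contributes to any
feature (asserted by a sentinel-injection test). Numeric variables (counts
and means) are z-scored with population statistics computed over unmasked
entries of non-test patients only; masked entries stay exactly 0;
zero-variance variables map to 0; binary/categorical variables pass through.

## Architecture

Scalars enter the variable-level recurrence through a learned per-variable
embedding `x·e_v + b_v` (dimension 8 by default) — a recurrent layer needs a
vector per step, and the bias term gives each variable an identity even when
its value is zero. The V variables of each real period are consumed in
fixed schema order (family blocks) by a GRU or LSTM of U units; additive
(one-hidden-layer tanh, default width 32) scoring of the per-variable
outputs followed by a mask-aware softmax over the value mask yields α and
the period context. Period contexts traverse a bidirectional recurrence
(same cell type and U per direction, concatenated to 2U) whose masked steps
carry state through unchanged — with left padding and zero initial state
this makes predictions exactly invariant to the amount of padding. Additive
scoring plus mask-aware softmax over the period mask yields β and the
summary; the summary concatenated with statics feeds an optional U-unit ReLU
dense layer and a sigmoid output. A real period in which *every* variable
is unrecorded receives zero attention and a zero context and is logged.

Degenerate inputs: an all-masked softmax row returns all zeros (the
consumer skips it); a patient with no real periods is an error.

Both cells and the entire backward pass are hand-written in NumPy (float32
for training) and checked against central finite differences in float64;
Adam is the optimizer. All randomness — initialization and batch shuffling
— flows from a single integer seed, so fits are bit-reproducible.

## Training protocol and defaults

Patient-level holdout: 10% test; 15% of the remainder validation (1000
patients → 765/135/100). Splits are simple random without stratification.
Grid search covers {GRU, LSTM} × {64, 128, 256, 512} units × {0, 1} dense
layers = 16 configurations, trained on the training set with early stopping
on validation ROC-AUC and selected by validation ROC-AUC (ties → fewer
parameters → grid order; failed configurations are recorded and skipped).
The winner is retrained from a fresh seeded initialization on
train+validation for the early-stopped number of epochs; an audit asserts
that no test patient ever enters a gradient batch, and normalization
statistics never touch test patients.

Defaults: Adam with learning rate 1e-2, batch size 64, early-stopping
patience 5, grid-search epoch budget half the final budget. The smaller
batch and larger step were chosen because with ~20–60 updates per epoch a
1e-3 / 256 regime leaves the attention mechanism effectively untrained for
tens of epochs, while 1e-2 / 64 reliably localizes a planted signal within
3–5 epochs; both are configurable. The classification threshold for
kappa/precision/recall is 0.5 and is stated in every report.

## Evaluation

Metrics: Cohen's kappa, trapezoidal ROC-AUC, PR-AUC (average precision),
precision and recall at the stated threshold, each with a 95% *percentile*
bootstrap interval over 1000 seeded resamples of the test set (resamples
with a single class are redrawn and counted). ROC-AUC is cross-checked in
tests against brute-force pairwise concordance, and kappa against the
closed-form contingency computation. Calibration uses twenty right-closed
bins of width 0.05 (p = 0 in the first, p = 1 in the last) with per-bin
observed proportions and class counts; the plot mirrors the
curve-plus-class-bars layout. Stratified reports (by sex, and by age band
at entry, default edges 65/75/85 — configurable since the published
grouping is not public) fan out the full metric set per stratum, flagging
small strata and omitting empty ones.

Baselines use each patient's *first observed year* (per-patient, so late
entrants remain usable), with missing cells imputed by training-set
mean/mode within integer-age × sex cells, falling back to age±2 within sex,
then sex only, then the global training value. Estimators are
scikit-learn's logistic regression and random forest and XGBoost's
classifier at library defaults (seeded; the defaults in force are recorded
in the run log via `get_params`), fitted on train+validation and evaluated
identically to the main model on the same split memberships.

## Attention reporting

Population maps average α and β over test patients with masked entries
excluded from the means; variables are ranked by mean α over real, recorded
slots ("overall contribution"; a β-weighted variant sits behind a flag —
the choice is display-level and both are computed from the same per-patient
maps), ties broken by schema order and flagged. Patient maps show the
top-5 variables per real year, min-max rescaled over the displayed values
only; raw weights are always reported alongside because variable-level
weights are numerically much smaller than time-level ones (they are spread
over ~220 recorded variables). Rendered heatmaps place variables in
columns with β as the final column; unobserved years are blank, not
zero-coloured.

## Synthetic cohort generator

The generator is the package's stand-in for a confidential primary-care
database and defines the study conditions under which the pipeline is
validated. Per patient: age at study start uniform on 56–99 (so ~20% enter
at their 65th birthday during follow-up); 10% of those already 65+ arrive
uniformly over the window (in-migrants); sex 56% female; SES quintile with
2% missing; loss to follow-up at 2%/year, censored at whole-year
granularity. A per-patient yearly visit intensity (uniform on 0.5–6)
drives Poisson visit counts; laboratory and measurement values are recorded
only in years with ≥1 visit, with per-analyte testing probability
increasing in the visit count — this produces the missingness the masks
must absorb. Chronic-disease and frailty diagnoses arise with small
per-year hazards, admissions and drug billings as Poisson counts.

Outcomes are drawn once per patient from a logistic model anchored at the
prediction index: log-odds = logit(base rate) + Σ_j effect_j ·
(recency-weighted history of planted variable j, mean-centered so the
intercept controls prevalence). Recency profiles: `last_year_only`,
`uniform`, and `decaying` (geometric, ratio 0.5), as normalized weights
over history years. The default plant puts log-odds effects (1.8, 1.5,
1.2) on three acute-event counts (i.i.d. Poisson(0.7) per year, so year-1
values carry no information about index-year values); these sizes were
fixed by computing the Bayes-optimal ROC-AUC of the generative model (~0.90)
so that "a good model recovers the signal" is a meaningful, attainable
check. Death dates fall in the final follow-up year and Z59.3/Z74 events
inside the outcome window (before death when both occur), keeping the
generator's anchor identical to the tensorizer's index rule. With all
effects zero the labelled outcome rate equals the configured base rate
exactly (tested at n = 10⁴ within binomial error).

What the generator does *not* emulate: realistic code frequencies or
prevalences of any real population, correlations between feature families,
seasonality, free text, or care-system effects. Passing the recovery
checks therefore demonstrates that the architecture, masking, protocol and
transparency layer work as specified — not that any particular clinical
performance would be attained on real data.

## Problem sizes and numerical choices

The recovery study runs at n = 5000 patients (≈4200 after eligibility),
U = 64, up to 8 epochs with patience 3 — sizes chosen so the full check
runs in minutes on a single CPU while leaving clear margin over the 0.85
recovery bar (measured ≈0.90 test ROC-AUC against a Bayes optimum of
≈0.90). The end-to-end demo uses n = 2000 and 6 epochs. Padding
invariance is asserted at 1e-5 (single precision), missing-value invariance
exactly (masks zero the values before they enter the network), attention
normalization at 1e-5. Bootstrap and split arithmetic use integer rounding
(`round(fraction × n)`).

## Known limitations

- Grid search over the full 16-point grid at U = 512 is expensive in pure
  NumPy; the demo and acceptance runs train a single configuration, and the
  grid machinery is exercised on small cohorts.
- One prediction index per patient (the last usable year); per-year
  multi-indexing is out of scope.
- Three outcomes are three separately trained models; no multi-task head.
- The attention-ranking choice (mean α vs β-weighted mean α) cannot be
  adjudicated against the published top-10 lists without the source data;
  both are provided.
- Bootstrap intervals are percentile, not BCa.
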