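# Methods

## Problem and scope

People with multiple long-term conditions (MLTC, two or more chronic
diagnoses) rarely fall into a single cluster of co-occurring diseases.
Given a fixed many-to-one partition of D=212 long-term conditions into
K=15 disease clusters, this package implements and evaluates seven rules
for mapping that partition onto individual patients, and asks how much
explanatory power each rule retains relative to using the individual
diseases themselves.

The package does **not** derive the clusters (they are an input), does
not handle clinical coding systems or record linkage, and treats all
times as ages in years — 1-year outcomes and onset medians need no
calendar.

## Assignment strategies

For a patient with N >= 2 distinct diseases and per-cluster counts
n_c (sum_c n_c = N):

| strategy     | value per cluster c            | notes |
|--------------|--------------------------------|-------|
| `ge1`/`ge2`/`ge3` | 1{n_c >= m}, m = 1, 2, 3  | any m >= 1 supported |
| `modal`      | one-hot at argmax_c n_c        | ties broken uniformly at random |
| `majority`   | 1{n_c / N > 0.5}               | strict; an exact half assigns nothing |
| `count`      | n_c                            | continuous in the regression |
| `proportion` | n_c / N (rows sum to 1)        | continuous in the regression |

Consequences that the test suite asserts as invariants: threshold
assignments are nested in m; `ge1`, `count` and `proportion` share one
nonzero pattern; a strict-majority cluster is always the unique mode (so
majority assignment implies an untied modal assignment).

The modal tie-break consumes one uniform draw per patient in patient-id
order from a stream seeded per run, so a seed reproduces the assignment
exactly; the tie rate is recorded because it is large in practice
(roughly a third of patients in cohorts with this co-occurrence
structure).

Pattern summaries per strategy: percentages of patients assigned to no,
one, or multiple clusters ("assigned" means a nonzero value, which makes
the `count`/`proportion` patterns identical to `ge1`); the percentage
fully represented (every disease inside some assigned cluster); and the
median/IQR of per-patient unassigned LTCs, N − sum of n_c over assigned
clusters.

## Outcome models

For each of three binary 1-year outcomes (death, any ED attendance, any
emergency admission) and each representation, a logistic regression

    logit P(y=1) = b0 + sum_c b_c z_c + covariates

is fitted by plain maximum likelihood (statsmodels Newton/IRLS,
convergence tolerance 1e-8, 100 iterations, BFGS fallback on a singular
Hessian; no penalisation).  z_c is the strategy's per-cluster value; the
reference model replaces the cluster block with 212 binary disease
indicators.  Covariates in every model: age (linear, continuous), gender
(female indicator), ethnicity dummies (reference = most frequent level)
and IMD decile dummies (reference = decile 1; a config switch makes IMD
continuous).  Deciles are ordinal with plausible nonlinearity, hence the
categorical default.

Patients flagged as de-registered during follow-up are excluded first so
every model sees the identical patient set; zero-variance columns are
dropped and recorded, and the parameter count k counts only estimated
coefficients (intercept included).  Models are compared by
AIC = 2k − 2 lnL; with equal input dimension across cluster strategies a
lower AIC means more explained variation.  Coefficients with |beta| > 15
are flagged as (quasi-)separated — at that magnitude the estimate is an
artefact of an empty cell, not an effect.  Non-convergence is reported,
never fatal: the comparison table still carries the cell, flagged.

Wald 95% intervals and two-sided p-values, unadjusted for multiplicity,
label "significant" terms downstream.

## Dispersion of adjusted odds ratios

Cluster-level adjusted odds ratios come from the `count`-strategy model
(interpreted per additional disease in the cluster); disease-level aORs
come from the 212-indicator model on the same patients.  Spread is
measured on the log-odds scale (symmetric for protective and harmful
effects): the within-cluster range is max − min of member-disease
log-aORs, the between-cluster range is max − min of the cluster-level
log-aORs, and the headline comparison is median within-range vs the
between-range.  Two variants are computed, over all estimated diseases
and over significant ones only.  Separation-flagged coefficients are
excluded from ranges in both variants: a pseudo-range of ±20 log-odds
from sparse cells would swamp any real heterogeneity signal.  Clusters
with fewer than two usable disease estimates are excluded from the
median, with a warning.

The significant-only variant is the sharper instrument for the
within-vs-between question: ranges over imprecise (non-significant)
estimates measure sampling noise, which does not vanish even when the
generator's within-cluster heterogeneity is switched off.

## Onset profiles

Disease-level median age at diagnosis uses each patient's earliest
recorded diagnosis age (duplicate rows collapse to the minimum on load);
even-sized samples take the midpoint of the central pair.  The
cluster-level median pools all events of member diseases
(event-weighted).  A disease-weighted alternative (median of member
medians) is available as a sensitivity switch, since either reading of
"median age at diagnosis of any disease in the cluster" is defensible.
Pooled cluster medians always lie within the range of member events'
ages, but not necessarily within the range of member-disease medians.

## Synthetic cohort generator

The generator produces cohorts with the structure the analysis assumes,
so the whole pipeline is testable without access to restricted EHR data.
Per patient:

- age ~ Normal(53, 18) truncated at 18 (mean/SD of a large English
  primary-care MLTC cohort); gender female with p=0.531; ethnicity
  5-level categorical (86.2% white); IMD decile with a mild gradient
  towards less deprived areas (~52% in deciles 1–5);
- LTC count L = 2 + NegBin(r=3.0, p=0.3158), which hits median 8 and
  IQR 5–11 exactly (scipy quantiles) — a right-skewed count matching the
  reference cohort's summary;
- a cluster propensity pi ~ Dirichlet(alpha * 1_K), alpha = 0.5 by
  default; L distinct diseases are drawn without replacement with weight
  base_prevalence(d) * pi(cluster(d)) via Gumbel top-k.  Small alpha
  concentrates a patient's diseases in few clusters; the mean
  concentration is monotone in alpha (tested), and alpha = 0.5 yields a
  modal tie rate near one third, matching what large cohorts show;
- base prevalence weights are log-uniform over two orders of magnitude
  (no public per-disease prevalences exist for this condition list; the
  spread produces the realistic mix of common and rare conditions);
- age at diagnosis per disease ~ Normal(onset_median_d, onset_spread_d)
  truncated to (0, age]; onset medians uniform on [25, 80] years and
  spreads on [6, 14] years across diseases.  Truncation is by rejection
  sampling (cap 1,000 rounds, then clamping) for bounded runtime.  Note
  the truncation biases observed medians below the generating median for
  diseases typically diagnosed late — the recovery test conditions on
  sufficiently old patients;
- outcomes y ~ Bernoulli(expit(b0 + covariate terms + sum_d gamma_d x_d))
  with baseline 1-year risks 2% (death), 18% (ED attendance), 8%
  (admission) and modest covariate effects (e.g. 0.08 log-odds per year
  of age for death).  Disease effects are gamma_d = mu_c(d) +
  Normal(0, tau): cluster means mu_c ~ Normal(0, 0.3) and within-cluster
  SD tau = 0.5 by default.  tau is the single knob for within-cluster
  effect heterogeneity; tau = 0 makes clusters exactly homogeneous;
- de-registration ~ Bernoulli(0.049), mirroring the ~4.9% follow-up
  exclusion of the reference cohort.

The choice cluster_effect_sd = 0.3 with tau = 0.5 places the regimes the
package is designed to distinguish on opposite sides of the dispersion
comparison: at tau = 0.5 the median within-cluster range (~2.85 * sqrt(
tau² + estimation noise) over ~14 members) clearly exceeds the
between-cluster range (~3 * 0.3), while at tau = 0 the significant-only
within-ranges collapse below it.

What the generator does **not** emulate: calendar-time disease
sequencing and order-of-onset structure, coding/recording incentives,
correlations between demographics and cluster propensities, and any real
per-disease prevalence or effect estimates.  Passing tests therefore
show that the pipeline recovers the structure it assumes — not that any
particular clinical finding would replicate.

## Problem sizes and numerical choices

Simulation-backed tests use n = 20,000 patients over 10 seeds for the
strategy-ordering and dispersion checks and n = 80,000 for effect
recovery; these sizes give stable orderings (AIC gaps of hundreds of
units) while keeping a full run in minutes on one CPU.  Determinism:
every random procedure takes an integer seed; catalog and cohort draws
use separate spawned streams, so one (config, seed) pair reproduces
byte-identical CSVs.  Medians/IQRs use numpy's linear interpolation.
The AIC identity 2k − 2 lnL is asserted exactly for every emitted fit.

## Known limitations

- Absolute AIC values depend on encodings and software; only orderings
  are meaningful, and only within one run on one patient set.
- The modal strategy's random tie-break makes its model fit seed-
  dependent; the tie rate is reported so users can judge the impact.
- The generator draws onset independently of outcomes given the disease
  set; onset profiling is purely descriptive.
- No interactions between clusters or with covariates, no multi-year
  follow-up, no discrimination/calibration metrics.
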