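# Methods

`neurolong` implements the longitudinal statistical machinery used in
two-arm cognitive-training trials with three measurement occasions
(pre-training, immediately post-training, ~3-month follow-up): a piecewise
linear mixed-effects model with monotonic/nonmonotonic change contrasts,
bootstrap-calibrated network-based statistics (NBS) on resting-state
connectivity, the surrounding QA and post hoc computations, and a
synthetic-cohort generator that makes all of it testable without subject
data.

## The piecewise mixed model

For outcome `y_ij` of subject `i` at visit `j`:

```
y_ij = b1 + b2*t_ij + b3*(t_ij - tb)*H(t_ij - tb)
     + b4*S_i + b5*S_i*t_ij + b6*S_i*(t_ij - tb)*H(t_ij - tb)
     + b7*A_i + b8*Bbar_i + b9*(B_ij - Bbar_i) + u_i + e_ij
```

with `tb` the breakpoint (by default the cohort-average time of the middle
visit), `H` the Heaviside step, `S_i` the treatment indicator, `A_i` age,
`Bbar_i`/`B_ij - Bbar_i` the between/within decomposition of a
time-varying covariate (depressive-symptom score; for edge models also
framewise displacement), `u_i ~ N(0, s_b^2)` a subject random intercept
and `e_ij ~ N(0, s_e^2)`.

**Estimation.** Full maximum likelihood, not REML, so that likelihoods of
bootstrap refits are directly comparable. Writing `lam = s_b^2 / s_e^2`,
the per-subject covariance `s_e^2 (I + lam J)` has a Sherman–Morrison
inverse, so `beta` and `s_e^2` are profiled out in closed form and the fit
reduces to a bounded one-dimensional search over `log lam` (Brent). The
boundary `s_b^2 = 0` is evaluated explicitly and clamped (with a runtime
warning) when it wins — this is the non-identifiable singleton-subject
case. Wald inference uses `Cov(beta) = s_e^2 (X' W X)^{-1}` with a
standard-normal reference (`|Z| > 1.96` ↔ p < .05), no small-sample df
correction. Covariate columns with zero variance are dropped (they are
collinear with the intercept); visits missing the outcome or a covariate
are excluded listwise by visit, not by subject.

**Contrasts.** Change hypotheses are defined on nominal timepoints but
evaluated at cohort-average times, `d1 = tb - 0` and `d2 = tbar3 - tb`:
TP2−TP1 loads `d1` on the pre-break slope(s), TP3−TP2 loads `d2` on the
post-break slope (base + hinge change), monotonic is their sum (net
change), nonmonotonic their difference (rise-then-return component).
Scope selects the slope family: control (`b2`, `b3`), treatment (both
families), or the group-by-time interactions only (`b5`, `b6`). Additivity
(`monotonic = tp2_minus_tp1 + tp3_minus_tp2`) holds exactly by
construction.

## Connectivity QA

Frames are censored when framewise displacement exceeds 0.5 mm or
standardized DVARS exceeds 1.8 (the DVARS cut can be re-derived as
median + 1.5·IQR of the pooled values); scans retaining under 4 minutes
fail QA; survivors are trimmed to the cohort-minimum frame count, keeping
the earliest surviving frames so the pipeline is deterministic without a
seed (a seeded random subsample is available by flag). Pearson
correlations are Fisher z-transformed; a perfect correlation raises by
default (it signals degenerate input) and can be capped at |r| = 1−1e−6
behind a flag. Each edge is finally scaled to zero mean / unit sample
variance across all scans pooled — both arms, all timepoints — because
the longitudinal edge models consume all scans jointly.

## Network-based statistics with a parametric bootstrap

Each of the 66 edges of a 12-ROI network gets the piecewise model above
(plus FD covariates); the edge-wise Wald Z field for the chosen contrast
is thresholded at |Z| > 1.96 and connected components of the resulting
graph are the candidate findings, sized in edges. Longitudinal data are
not exchangeable, so permutation calibration is invalid; instead the null
distribution of the maximal component size is estimated by a parametric
bootstrap: per replicate, every edge is re-simulated from its fitted model
with all group-by-time coefficients zeroed (the baseline group offset and
covariate effects are nuisance and retained; variance components at their
fitted, per-edge values; the observed subject-visit missingness reproduced
exactly), refitted, thresholded, and the max component size recorded.
Component p-values use the add-one rule `(1 + #{null >= size}) / (1 + B)`,
with `B = 10,000` at study scale and ~200 in test presets.

Numerical choices worth knowing:

- Bootstrap and observed edge fits share one vectorised profiled-ML path
  over a fixed `lam` grid (`{0} ∪ geomspace(1e-4, 1e4, 49)`), so the
  observed field and its null are computed by literally the same
  estimator; the grid costs a little likelihood (< ~0.5 nats) but moves
  contrast Z statistics by < 0.05, and the familywise error calibration is
  unaffected because both sides of the comparison use the grid.
- Edges are simulated independently under the null (per-edge models, no
  cross-edge covariance). Real edge fields are correlated, so the
  component-size null can be mildly mis-calibrated in principle; the
  type-I acceptance simulation (independent edges) cannot detect that
  limitation by construction.
- Replicates in which more than 1% of edge refits are degenerate are
  dropped and logged; with sane inputs none are.

## Post hoc computations

- **2 SD classification:** a subject's change (per window: TP1→TP2,
  TP2→TP3, monotonic, nonmonotonic) is flagged when it lies strictly
  outside mean ± 2·SD (sample SD) of the *other* arm's change
  distribution. Strict inequality and n−1 SD are conventional choices the
  source procedure leaves open. On a matched null ~4.6% of subjects flag
  by chance (two-tailed 2 SD mass); no p-values are attached, by design,
  since regions are selected by the group analysis.
- **Effect sizes:** the fitted model's group trajectory at cohort
  covariate means, evaluated at the average visit times; change over the
  requested window (the mid-study excursion for nonmonotonic regions,
  final-minus-baseline for monotonic ones — both are exported since
  "overall change" is ambiguous for transient effects), normalised by the
  arm's observed baseline mean.
- **Reflection:** nonmonotonic trajectories are aligned with monotone
  behavioural change by reflecting the final visit across the mid-study
  value, `y3 -> 2*y2 - y3`; an involution on TP3, identity when
  TP3 = TP2.

## Behavioural battery and associations

Continuous demographics pass a Shapiro–Wilk gate (alpha .05) routing to a
pooled-variance t-test or Mann–Whitney U (exact for n ≤ 8 per group
without ties). Categorical tables use an in-package two-sided Fisher exact
test (minimum-likelihood rule, 1e-7 tolerance on probability ties) or the
likelihood-ratio G test; because published tables in this literature
sometimes print Pearson X² p-values under a likelihood-ratio heading, both
statistics are always returned. Scaled scores (mean 10, SD 3) convert to
percentiles by integer rounding then the normal CDF — the rounding-first
convention matches normative lookup tables (8.2 → 25%, 9.8 → 50%). No
correction is applied across behavioural measures (exploratory battery).

Brain-behaviour association residualizes the behavioural score once,
cohort-wide, by OLS on age/education/IQ/mood, then adds its
between/within pair to the model; the within-subject coefficient's Wald
test is the association statistic. In nonmonotonic mode only the outcome
is reflected, not the score (the literal reading of the procedure).
Seed-based maps Bonferroni-correct across seeds (.05/10 = .005 for the
ten-seed analysis).

## The synthetic cohort: what it does and does not emulate

Defaults are the study's stated design: 31 treatment / 29 control
enrolled; visits at 0/9/21 weeks with truncated-normal jitter (SD 0, 0.8,
1.6 weeks, ordering preserved); per-timepoint retention equal to the
reported scan counts (treatment 29/27/17 of 31; control 28/24/23 of 29),
missing completely at random, with an optional monotone-dropout mode; age
~ N(40, 12²); BDI as a subject-level mean (N(18, 10²), truncated at 0)
plus per-visit noise (SD 3) so the between/within decomposition is
non-trivial. Default fixed effects give the treatment arm a 0.012 mm/week
rise reversing after the breakpoint (a ~0.11 mm excursion on a 2.5 mm
baseline, the reported magnitude), with `s_b = 0.12` mm and `s_e = 0.05`
mm. One global seed fans out to per-subject substreams, so subsets are
reproducible. Scan simulation draws iid Gaussian frames from a target
covariance plus motion traces with Bernoulli spike contamination (spiked
frames exceed both censoring thresholds and carry large signal
perturbations).

Not emulated: BOLD spectral content and autocorrelation, hemodynamics,
informative (outcome-dependent) dropout, spatial surface geometry, and
cross-edge covariance of connectivity. A green test therefore establishes
that the estimators are correct and calibrated for the stated generative
world, not that they are robust to those real-data features.

## Known limitations

- Random intercepts only (no random slopes), matching the source model.
- The headline neuroimaging findings of the motivating study depend on
  unreleased MRI data; the pipeline reproduces the *procedures* and their
  calibration, and the in-paper demographic statistics, not those maps.
- Percent effect sizes divide by the observed baseline mean and are
  undefined for zero-baseline outcomes (an error is raised).
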