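# neurolong

Longitudinal statistics for two-arm brain-training trials: piecewise
linear mixed-effects models with monotonic/nonmonotonic change contrasts,
bootstrap-calibrated network-based statistics (NBS) on resting-state
functional connectivity, connectivity QA (motion scrubbing, frame
trimming, Fisher z, edge standardization), post hoc single-subject
classification and effect sizes, a demographic/behavioural test battery,
and a synthetic-cohort generator with known ground truth.

It is aimed at analysts of clinical-trial neuroimaging data with three
measurement occasions (pre-training, post-training, follow-up), unequal
visit timing, and attrition — the setting where repeated-measures ANOVA
breaks down and permutation-based NBS is invalid because longitudinal
observations are not exchangeable.

## The model

The outcome of subject *i* at visit *j* follows a random-intercept
piecewise linear model with a slope change (Heaviside hinge) at the
mid-study visit time t̃:

y_ij = β₁ + β₂·t_ij + β₃·(t_ij−t̃)H(t_ij−t̃) + β₄·S_i + β₅·S_i·t_ij
     + β₆·S_i·(t_ij−t̃)H(t_ij−t̃) + β₇·A_i + β₈·B̄_i + β₉·(B_ij−B̄_i)
     + b_i + e_ij

with treatment indicator S, age A, a between/within-decomposed
time-varying covariate B (mood score; framewise displacement for edge
models), b_i ~ N(0, σ_b²) and e_ij ~ N(0, σ_e²), fitted by full maximum
likelihood (profiled over the variance ratio). Change hypotheses are Wald
contrasts of the slope terms at the cohort-average visit times:
TP2−TP1, TP3−TP2, their sum (**monotonic** net change) and their
difference (**nonmonotonic** rise-then-return). For connectivity, the same
model runs per edge; supra-threshold (|Z| > 1.96) edges form components
whose familywise significance comes from a parametric bootstrap of the
maximal component size under the group-by-time null.

See `docs/methods.md` for the estimation details, numerical choices and
known limitations.

## Worked example

```python
import numpy as np
from neurolong import (CohortParams, generate_cohort,
                       fit_piecewise_lme, contrast_table)
from neurolong.posthoc import effect_size_region

cohort, truth = generate_cohort(CohortParams(seed=1))
fit = fit_piecewise_lme(cohort, "thickness")
print(contrast_table(fit).query("scope == 'between'").round(4))
```

prints

```
        label   scope  estimate     se       z      p
tp2_minus_tp1 between    0.1612 0.0220  7.3413 0.0000
tp3_minus_tp2 between   -0.2071 0.0261 -7.9350 0.0000
    monotonic between   -0.0458 0.0240 -1.9077 0.0564
 nonmonotonic between    0.3683 0.0418  8.8053 0.0000
```

The default cohort (31 treatment / 29 control, visits near 0/9/21 weeks
with the stated attrition) injects a transient treatment effect: cortical
thickness rises 0.012 mm/week before the breakpoint and falls back after
it. The contrast table reads exactly that way — strong between-group
TP2−TP1 and TP3−TP2 changes of opposite sign, a large **nonmonotonic**
contrast (estimate 0.37 mm is the rise-plus-return total over both
segments), and no significant net (monotonic) change. The fitted variance
components (σ_b = 0.124, σ_e = 0.053 mm) recover the generative 0.12/0.05,
and

```python
effect_size_region(cohort, "thickness", group=1, pattern="nonmonotonic")
# -> (0.133 mm, 5.5 % of the 2.5 mm baseline)
```

matches the injected ~0.11 mm excursion within sampling error.

The full chain — scan simulation, scrubbing/trimming, Fisher-z
connectivity, edge standardization, NBS with B bootstrap replicates,
post hoc flags, behavioural battery, associations — runs from the shell:

```sh
neurolong run-all --out results/ --seed 1 -B 200
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch at test presets (default cohort
design, B = 200) — simulation, connectivity QA, all mixed-model stages,
the bootstrap-calibrated network statistics, post hoc and behavioural
computations — and writes the acceptance JSON to `--out`.
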