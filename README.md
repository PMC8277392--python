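# mnarsens

Sensitivity analysis for outcome data **missing not at random (MNAR)** in
two-arm pre/post randomized trials, plus a meta-analysis engine for
**differential attrition** across trials.

Mobile-health and other remotely delivered RCTs routinely lose far more
participants from the active arm than from a waitlist control. When the
people who drop out are the ones doing worst, the missingness depends on the
unobserved outcome itself — MNAR — and standard missing-data machinery
(multiple imputation, maximum likelihood) silently assumes it doesn't (MAR).
`mnarsens` implements two complementary sensitivity analyses for that
situation, and the study-level analysis that motivates them.

## What it computes

**Differential-attrition meta-analysis** (`mnarsens.meta_attrition`).
Each trial contributes a 2×2 dropout table. The study effect is the log odds
ratio of dropping out (active vs passive), y_i = ln[(a/b)/(c/d)] with
variance 1/a+1/b+1/c+1/d, or the Peto approximation (O−E)/V for sparse
tables; a 0.5 continuity correction is applied to all four cells of studies
with an empty cell. Effects are pooled with inverse-variance random effects,
weights 1/(v_i+τ²), with τ² estimated by REML (default) or DerSimonian–Laird;
heterogeneity is reported as I² = 100·τ²/(τ²+s²) with a Q-profile CI.
Leave-one-out re-pooling, a CI-overlap outlier rule, mixed-effects
meta-regression on study moderators, and the classic fixed-effect Peto pool
Σ(O−E)/ΣV round out the engine. A 36-study attrition table from published
smartphone-intervention RCTs is packaged as `mnarsens.load_packaged_attrition_table()`.

**Pattern-mixture offset analysis** (`mnarsens.pattern_mixture`).
Missing posttests are multiply imputed (proper Bayesian linear regression on
pretest, arm, and covariates; m = 100 by default), then every imputed value
is shifted by

    imputed ← imputed + δ · SD_model

where SD_model is the residual SD of `posttest ~ pretest + arm` among
completers and δ ∈ {0, 0.2, 0.5, 0.8, 1.1, 1.4} (0 = MAR anchor). Each
completed dataset is analyzed by ANCOVA (`posttest ~ pretest + arm`) and the
arm coefficients are pooled by Rubin's rules with Barnard–Rubin degrees of
freedom. The result is a tipping-point table: how bad must the unobserved
outcomes be before the treatment effect loses significance?

**Fixed-value replacement analysis** (`mnarsens.fixed_replacement`).
Residualized change (observed minus pretest-predicted posttest) is computed
for completers; missing subjects all receive one assumed residual —
complete-case, worst observed, or mean + 0.2/0.5/0.8 SD in the worsening
direction — and the arms are compared with a two-sample rank-sum test
(midranks; exact permutation null for small groups, tie-corrected normal
approximation otherwise).

**Synthetic trials** (`mnarsens.synthetic_data`) generate all of the above's
inputs with known truth, including an MNAR mechanism in which dropouts'
hidden outcomes deteriorate by a configurable number of residual SDs — the
exact data-generating counterpart of the δ-offset model.

## Worked example

```python
import mnarsens as mn

# 1. How differential is attrition across 36 published trials?
records = mn.load_packaged_attrition_table()
effects = mn.compute_effects(records, "standard", correction=True)
pooled = mn.pool_random_effects(effects)
print(f"k={pooled.k}  OR={pooled.odds_ratio:.2f} "
      f"(95% CI {pooled.or_ci[0]:.2f}-{pooled.or_ci[1]:.2f})  "
      f"I2={pooled.i2:.2f}%  p={pooled.p:.2g}")

# 2. Would a trial's effect survive MNAR dropout?
cfg = mn.TrialSimConfig(mechanism="MNAR_on_posttest", mnar_shift=0.8, seed=1)
trial = mn.simulate_trial(cfg)
results = mn.run_sensitivity(trial, m=100, seed=2)
print(mn.sensitivity_table(results).round(3).to_string(index=False))
```

Output:

```
k=36  OR=1.94 (95% CI 1.50-2.51)  I2=53.85%  p=4.9e-07
model  delta  estimate    se      df     p
  MAR    0.0    -0.235 0.105 126.454 0.027
 0.20    0.2    -0.212 0.105 127.344 0.046
 0.50    0.5    -0.177 0.107 131.552 0.099
 0.80    0.8    -0.142 0.109 138.941 0.195
 1.10    1.1    -0.108 0.113 149.033 0.342
 1.40    1.4    -0.073 0.118 161.198 0.536
```

Randomized participants were about twice as likely to drop out of active
arms as out of waitlists (pooled OR 1.94), with moderate heterogeneity —
exactly the setting where MNAR is plausible. In the simulated trial (true
MNAR deterioration of 0.8 residual SDs among dropouts), the MAR-based MI
estimate of the treatment effect, −0.235 z-units of distress (p = .027),
attenuates as the assumed deviation δ grows and is no longer significant
from δ = 0.5 upward: the headline result is robust only to small MNAR
departures.

The same analyses are available from the shell:

```bash
mnarsens meta --outliers --peto-fixed --moderator total_n --out out/meta
mnarsens simulate --mechanism MNAR_on_posttest --mnar-shift 0.8 --seed 1 --out out/sim
mnarsens pmm --input out/sim/trial.csv --m 100 --seed 2 --out out/pmm
mnarsens fixedrep --input out/sim/trial.csv --out out/fixedrep
```

Each command writes CSV tables plus a `manifest.json` recording the options
and seed, so any run can be reproduced exactly.

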