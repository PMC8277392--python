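# Methods notes

This note records the statistical models implemented in `mnarsens`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that a maintainer would otherwise
have to reverse-engineer.

## Differential-attrition meta-analysis

**Effect sizes.** For a study with dropout/completion counts (a, b) in the
active arm and (c, d) in the passive arm, the standard effect is
y = ln[(a/b)/(c/d)], v = 1/a+1/b+1/c+1/d. The continuity correction adds 0.5
to *all four* cells of a study containing a zero cell and leaves clean
studies untouched. The Peto effect is (O−E)/V with O = a,
E = n₁(a+c)/N and hypergeometric variance V = n₁n₂(a+c)(b+d)/(N²(N−1)); it
is computed on raw counts and tolerates single zero cells, but is undefined
for studies with no (or only) events, which are excluded from Peto pooling
with an explicit error unless batch mode is asked to skip them.

**Pooling.** Inverse-variance random effects with weights 1/(vᵢ+τ²) and Wald
CIs on the log scale. τ² is estimated by REML (default) via bounded scalar
maximization of the restricted likelihood, or by the DerSimonian–Laird
moment estimator; both truncate at 0, and the DL form is generalized to the
moderator case as (Q_E−(k−p))/tr(P). REML was made the default because it is
the default of the standard R meta-analysis software this engine was
validated against; the validation froze that software's estimates (to ≥6
decimals) into the test suite as an independent oracle. No Knapp–Hartung
small-sample adjustment is applied: the reference results use plain Wald
inference, and reproducing their CI widths requires it.

**Heterogeneity.** I² = 100·τ²/(τ²+s²) with the Higgins–Thompson typical
within-study variance s² = (k−1)Σw/((Σw)²−Σw²), w = 1/vᵢ. Its CI inverts the
generalized Q statistic (Q-profile): solve Q(τ²) = χ²₀.₉₇₅ and χ²₀.₀₂₅ with
k−1 df, then map the τ² bounds through the I² formula. The Q-profile method
was chosen because it reproduces the published interval and needs no
normality of the τ² estimate.

**Diagnostics.** Leave-one-out re-pools k times. The outlier rule flags a
study when its individual 95% CI lies entirely outside the pooled 95% CI; a
convenience re-pool without flagged studies is provided. Meta-regression
fits a single fixed moderator slope with a random study intercept, using the
same τ² estimator, and reports a Wald z-test in log-OR units.

**Classic Peto pool.** Σ(O−E)/ΣV with SE 1/√ΣV (fixed-effect), kept as a
separate entry point for sparse tables. On the packaged 36-study table the
random-effects pool of corrected standard log ORs gives OR 1.94 and the
classic Peto pool gives OR 2.22; both published pooled figures correspond to
these two computations, so both are exposed.

**Review coding.** Per-arm attrition percentages are averaged *unweighted*
across studies (this is the only reading that reproduces the published
summary percentages). "Used ML or MI" is 1 if either column says Yes;
"Unclear" counts as No. Note two internal inconsistencies of the published
material, which the package reproduces as printed in its table: the table's
mean total sample size is 143.47 (text: 143.53) and it contains three
zero-attrition studies (text: two). The packaged fixture is the printed
table, transcribed verbatim; summaries derived from it are the reproducible
quantities.

## Pattern-mixture offset analysis

**Imputation.** One incomplete variable (posttest) means the full joint
multivariate-normal MI engine reduces to Bayesian normal linear regression,
so that is what is implemented — direct conjugate draws, no Markov chain and
hence no convergence tuning: per imputation, σ²* ~ RSS/χ²(n−p), β* ~
N(β̂, σ²*(XᵀX)⁻¹), then one predictive noise draw per missing value.
Predictors are pretest, arm, and any user covariates. m defaults to 100.
Subjects missing the pretest are excluded at load time with a warning (the
entire procedure conditions on pretest).

**Offset.** δ·SD_model is added to imputed entries only, in the direction
that worsens the outcome (added for lower-is-better outcomes, subtracted
otherwise). SD_model is the completer residual SD of
`posttest ~ pretest + arm` — *with* the group term, the more conservative
scale, since omitting it inflates the residual SD with the treatment effect
and overstates each δ step. The offset is applied identically in both arms
(the deviation model does not condition on arm); an arm-specific variant is
available for exploration (`OffsetSpec` can be applied to arm-subset masks).
The same m imputations are reused across the δ grid, so the δ-profile is
free of between-draw Monte-Carlo noise; `reuse_draws=False` re-imputes per δ.

**Analysis and pooling.** Per completed dataset, OLS ANCOVA
`posttest ~ pretest + arm`; Rubin's rules with total variance
W̄ + (1+1/m)B and Barnard–Rubin degrees of freedom (complete-data df n−p),
two-sided t p-values. The default δ grid {0, 0.2, 0.5, 0.8, 1.1, 1.4}
follows effect-size convention (small to very large deviations), with 0 as
the MAR anchor.

## Fixed-value replacement analysis

Residualized change is the observed posttest minus the posttest predicted
from pretest by OLS on completers pooled across arms — deliberately
*without* the group term, unlike SD_model above. The two scales serve
different roles: the replacement scenarios describe deviations on the raw
outcome scale, whereas the offset scale should not credit the intervention's
own effect; the distinction can change a significance call and is therefore
kept explicit in the API. With an intercept in the prediction model the
completer residuals average to zero by construction (asserted to 1e-10).

Scenarios: complete-case (missing excluded); worst-case (the maximum
observed residual for lower-is-better outcomes, minimum otherwise — taken
over completers only, avoiding circularity); small/medium/large = mean +
0.2/0.5/0.8 SD of the completer residuals, sign-flipped for higher-is-better
outcomes. The same replacement value goes to missing subjects in both arms.
Simple change scores (post − pre) are available behind a flag.

**Testing.** The group comparison is between independent arms, so a
two-sample rank-sum (Mann–Whitney) test is used. Ties get midranks. For
groups of ≤8 the null distribution is computed exactly by subset-sum
dynamic programming over doubled ranks (the test suite checks it against
brute-force enumeration of all assignments); larger samples use the normal
approximation with tie-corrected variance and a 0.5 continuity correction.
A degenerate pooled sample (zero rank variance) returns p = 1. Mean rank,
SD of ranks, and SE = SD/√n are reported per group.

## Synthetic-data generator

`simulate_trial` draws pretest ~ N(0,1) and posttest = b·pretest +
effect·active + ε, ε ~ N(0, residual_sd²), with b = r·s/√(1−r²) so that the
default r = 0.76, s = 0.65 give the control arm unit posttest variance (both
timepoints on the z scale). Defaults mirror the reference trial conditions:
228 active / 115 passive (~2:1), marginal missing rates 0.601 / 0.417, a
lower-is-better distress-like outcome, and treatment effect −0.35 outcome
SDs. Missingness mechanisms:

- **MCAR** — per-arm constant probability.
- **MAR_on_pretest** — logit P(miss) = a + slope·pretest (slope default 1);
  the intercept is solved per arm by root finding so the *realized sample's*
  expected missing rate equals the target exactly.
- **MNAR_on_posttest** — two components. (i) `mnar_shift`: dropouts'
  hidden outcomes deteriorate by shift·residual_sd after dropout; this is
  precisely the pattern-mixture data-generating model, for which offset
  analysis at δ = shift is consistent. (ii) `mnar_slope` (default 0):
  logistic selection on the to-be-hidden outcome value, calibrated to the
  marginal rates like MAR. With a nonzero slope no single δ is exactly
  correct — selection-type MNAR is *not* a location shift — so the default
  study condition for recovery checks is the pure shift mechanism.

Because shifting dropouts' outcomes changes the estimand, the generator
exposes `true_itt_effect`: the expected ANCOVA contrast on actual outcomes,
treatment_effect + (p_miss_active − p_miss_passive)·shift·residual_sd.
Bias checks compare against that closed form; the MAR analysis (δ = 0)
recovers the pre-deterioration effect instead, which is exactly the
MNAR bias the toolkit exists to expose.

What the generator does **not** emulate: item-level missingness, missing
pretests, longitudinal (3+ timepoint) designs, cluster randomization,
floor/ceiling effects, and non-normal outcomes. Passing tests therefore
demonstrate correctness of the procedures under idealized Gaussian
conditions, not robustness of conclusions on any particular real trial.

## Problem sizes in the test suite

The simulation-based checks use trial sizes matching the reference
conditions (343 subjects; n = 2000 for the monotonicity checks), m = 20–50
imputations, and 200 replicates for bias properties, with fixed seeds
throughout; the whole suite runs in seconds. Monte-Carlo tolerances are
stated as multiples of the empirical Monte-Carlo SE over replicates.

## Known limitations

- REML optimization is a bounded scalar search; pathological likelihoods
  with multiple local maxima (possible at k ≤ 3 with extreme variance
  ratios) are not specially handled.
- The Q-profile CI is reported only when both bounds can be bracketed.
- Rank-sum "exact" mode is capped at 8 per group for predictable runtime;
  the cap is a constant (`EXACT_MAX_GROUP`), not configurable per call.
- The offset analysis assumes the imputation model is the analysis model
  plus covariates; uncongenial imputation models are out of scope.
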