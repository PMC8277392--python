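"""Synthetic trial and study-table generators with known truth.

``simulate_trial`` emulates a two-arm pre/post mHealth-style RCT: a z-scaled
continuous distress outcome (lower is better), ~2:1 randomization, and heavy,
group-differential posttest missingness. Its defaults mirror the reference
trial conditions: 228 active / 115 passive, marginal missing rates 60.1% /
41.7%, residual SD 0.65. Three missingness mechanisms are available:

* ``MCAR`` — constant per-arm probability;
* ``MAR_on_pretest`` — logistic in the observed pretest, intercept calibrated
  per arm so the marginal rate hits the target;
* ``MNAR_on_posttest`` — dropouts' (hidden) outcomes deteriorate by
  ``mnar_shift`` residual SDs, optionally combined with logistic selection on
  the to-be-hidden posttest (``mnar_slope``; default 0, i.e. the pure
  pattern-mixture mechanism for which offset analysis at delta = mnar_shift
  is consistent).

``simulate_study_table`` draws study-level attrition 2x2 tables around a true
pooled log OR with between-study variance tau2, for exercising the
meta-analysis stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .meta_attrition import StudyRecord
from .pattern_mixture import TrialDataset

__all__ = [
    "TrialSimConfig",
    "MetaSimConfig",
    "simulate_trial",
    "simulate_study_table",
    "true_itt_effect",
]


@dataclass(frozen=True)
class TrialSimConfig:
    """Generating parameters for a two-arm pre/post trial.

    ``treatment_effect`` shifts the active arm's posttest in outcome-SD units
    (negative improves a lower-is-better outcome). ``pre_post_correlation``
    and ``residual_sd`` jointly set the pretest slope; the defaults give the
    control arm a posttest SD of ~1 so both timepoints are on the z scale.
    ``mnar_shift`` is the deterioration of dropouts' hidden outcomes in
    residual-SD units; ``mnar_slope`` adds logistic selection on the hidden
    posttest value.
    """

    n_active: int = 228
    n_passive: int = 115
    treatment_effect: float = -0.35
    pre_post_correlation: float = 0.76
    residual_sd: float = 0.65
    miss_prob_active: float = 0.601
    miss_prob_passive: float = 0.417
    mechanism: str = "MCAR"
    mnar_shift: float = 0.0
    mnar_slope: float = 0.0
    mar_slope: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.miss_prob_active < 1 and 0 <= self.miss_prob_passive < 1):
            raise ValueError("missingness probabilities must be in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not -1 < self.pre_post_correlation < 1:
            raise ValueError("pre_post_correlation must be in (-1, 1)")
        if self.mechanism not in ("MCAR", "MAR_on_pretest", "MNAR_on_posttest"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def pretest_slope(self) -> float:
        r, s = self.pre_post_correlation, self.residual_sd
        return r * s / math.sqrt(1 - r**2)


@dataclass(frozen=True)
class MetaSimConfig:
    """Generating parameters for a table of study-level attrition counts."""

    k: int = 36
    mu_log_or: float = 0.7
    tau2: float = 0.2
    itt_size_range: tuple[int, int] = (20, 250)
    base_dropout_prob: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if not 0 <= self.base_dropout_prob < 1:
            raise ValueError("base_dropout_prob must be in [0, 1)")


def _calibrate_intercept(driver: np.ndarray, slope: float, target: float) -> float:
    """Intercept a with mean(expit(a + slope*driver)) = target on this sample."""
    if target == 0:
        return -np.inf
    if slope == 0:
        return float(logit(target))
    f = lambda a: float(np.mean(expit(a + slope * driver))) - target  # noqa: E731
    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("missingness calibration failed: target rate unreachable")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def simulate_trial(config: TrialSimConfig) -> TrialDataset:
    """Draw one trial; returns a TrialDataset (lower_is_better outcome).

    The returned object's frame (``to_frame``) is the observed data; the
    complete pre-deterioration and actual outcomes are attached as
    ``posttest_full`` and ``posttest_true`` attributes for oracle analyses.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_active + config.n_passive
    active = np.zeros(n)
    active[: config.n_active] = 1.0
    pretest = rng.standard_normal(n)
    posttest = (
        config.pretest_slope * pretest
        + config.treatment_effect * active
        + config.residual_sd * rng.standard_normal(n)
    )

    miss = np.zeros(n, dtype=bool)
    targets = {1.0: config.miss_prob_active, 0.0: config.miss_prob_passive}
    for arm_val, target in targets.items():
        in_arm = active == arm_val
        if config.mechanism == "MCAR":
            prob = np.full(int(in_arm.sum()), target)
        elif config.mechanism == "MAR_on_pretest":
            a = _calibrate_intercept(pretest[in_arm], config.mar_slope, target)
            prob = expit(a + config.mar_slope * pretest[in_arm])
        else:  # MNAR_on_posttest: selection on the to-be-hidden outcome
            a = _calibrate_intercept(posttest[in_arm], config.mnar_slope, target)
            prob = expit(a + config.mnar_slope * posttest[in_arm])
        miss[in_arm] = rng.random(int(in_arm.sum())) < prob

    posttest_true = posttest.copy()
    if config.mechanism == "MNAR_on_posttest" and config.mnar_shift:
        # dropouts deteriorate after leaving: worse = higher distress
        posttest_true[miss] += config.mnar_shift * config.residual_sd

    observed = posttest_true.copy()
    observed[miss] = np.nan
    data = TrialDataset(
        subject_id=np.array([f"s{i:04d}" for i in range(n)]),
        arm=np.where(active == 1.0, "active", "passive"),
        pretest=pretest,
        posttest=observed,
        direction="lower_is_better",
    )
    data.posttest_full = posttest  # pre-deterioration outcomes
    data.posttest_true = posttest_true  # actual outcomes incl. deterioration
    return data


def true_itt_effect(config: TrialSimConfig) -> float:
    """Expected ANCOVA arm contrast on the actual (post-deterioration) outcomes.

    Shifting dropouts' outcomes moves each arm's mean by its missingness rate
    times the shift, so the intention-to-treat contrast is
    treatment_effect + (p_miss_active - p_miss_passive) * mnar_shift * residual_sd.
    """
    shift = config.mnar_shift if config.mechanism == "MNAR_on_posttest" else 0.0
    return config.treatment_effect + (
        config.miss_prob_active - config.miss_prob_passive
    ) * shift * config.residual_sd


def simulate_study_table(config: MetaSimConfig) -> list[StudyRecord]:
    """Draw k studies with true study log ORs ~ Normal(mu_log_or, tau2).

    The passive arm drops out with the base probability; the active arm's
    probability comes from the study's log OR on the odds scale. Dropout
    counts are binomial.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.itt_size_range
    records = []
    base = config.base_dropout_prob
    for i in range(config.k):
        theta = rng.normal(config.mu_log_or, math.sqrt(config.tau2))
        n1 = int(rng.integers(lo, hi + 1))
        n2 = int(rng.integers(lo, hi + 1))
        p_passive = base
        p_active = float(expit(logit(base) + theta)) if base > 0 else 0.0
        records.append(
            StudyRecord(
                study_id=f"sim{i:03d}",
                n_itt_active=n1,
                drop_active=int(rng.binomial(n1, p_active)),
                n_itt_passive=n2,
                drop_passive=int(rng.binomial(n2, p_passive)),
                moderators={"true_log_or": float(theta)},
            )
        )
    return records


def trial_to_frame(data: TrialDataset) -> pd.DataFrame:
    """Observed-data frame for writing to CSV."""
    return data.to_frame()
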