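"""Meta-analysis of differential attrition in two-arm randomized trials.

Each study contributes a 2x2 table (dropout vs completion, active vs passive
arm). Differential attrition is summarized as a log odds ratio, with positive
values indicating higher attrition in the active arm. Study effects are pooled
with an inverse-variance random-effects model; between-study variance tau^2 is
estimated by REML (default) or DerSimonian-Laird, heterogeneity is expressed as
I^2 with a Q-profile confidence interval, and moderators are assessed with
mixed-effects meta-regression. A classic fixed-effect Peto pool
(sum(O-E)/sum(V)) is available for sparse tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StudyRecord",
    "EffectSize",
    "PooledEstimate",
    "MetaRegressionFit",
    "ReviewSummary",
    "UndefinedEffectError",
    "compute_log_or",
    "compute_peto_log_or",
    "continuity_correct",
    "pool_random_effects",
    "pool_peto_fixed",
    "leave_one_out",
    "detect_outliers",
    "meta_regress",
    "summarize_review",
    "forest_data",
]

Z975 = stats.norm.ppf(0.975)


class UndefinedEffectError(ValueError):
    """Raised when a study's 2x2 table does not admit the requested effect size."""


@dataclass(frozen=True)
class StudyRecord:
    """One RCT's attrition counts plus optional coded design features.

    ``moderators`` holds study-level covariates for meta-regression and review
    summaries (e.g. ``total_n``, ``overall_attrition``, ``tested_diff``,
    ``detected_diff``, ``used_ml_or_mi``, ``method``).
    """

    study_id: str
    n_itt_active: float
    drop_active: float
    n_itt_passive: float
    drop_passive: float
    moderators: dict = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.drop_active <= self.n_itt_active):
            raise ValueError(
                f"{self.study_id}: drop_active must be in [0, n_itt_active]"
            )
        if not (0 <= self.drop_passive <= self.n_itt_passive):
            raise ValueError(
                f"{self.study_id}: drop_passive must be in [0, n_itt_passive]"
            )

    @property
    def complete_active(self) -> float:
        return self.n_itt_active - self.drop_active

    @property
    def complete_passive(self) -> float:
        return self.n_itt_passive - self.drop_passive

    @property
    def total_n(self) -> float:
        return self.n_itt_active + self.n_itt_passive

    def cells(self) -> tuple[float, float, float, float]:
        """(drop_active, complete_active, drop_passive, complete_passive)."""
        return (
            self.drop_active,
            self.complete_active,
            self.drop_passive,
            self.complete_passive,
        )


@dataclass(frozen=True)
class EffectSize:
    study_id: str
    yi: float  # log odds ratio; positive = more attrition in the active arm
    vi: float  # sampling variance of yi
    method_tag: str = "standard"  # {"standard", "peto"}
    corrected: bool = False

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.yi)

    def ci(self) -> tuple[float, float]:
        half = Z975 * math.sqrt(self.vi)
        return self.yi - half, self.yi + half


@dataclass(frozen=True)
class PooledEstimate:
    mu: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float | None
    k: int
    p: float
    method: str
    i2_ci: tuple[float, float] | None = None
    tau2_ci: tuple[float, float] | None = None
    label: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.mu)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class MetaRegressionFit:
    moderator_name: str
    B: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    intercept: float
    tau2: float
    k: int
    method: str


@dataclass(frozen=True)
class ReviewSummary:
    n_studies: int
    mean_total_n: float
    sd_total_n: float
    mean_attrition_active: float  # percent, unweighted study mean
    sd_attrition_active: float
    mean_attrition_passive: float
    sd_attrition_passive: float
    n_with_attrition: int
    n_tested_diff: int
    n_detected_diff: int
    n_ml_mi: int


# ---------------------------------------------------------------------------
# per-study effect sizes


def continuity_correct(record: StudyRecord) -> StudyRecord:
    """Add 0.5 to all four cells of a study containing an empty cell.

    Studies without a zero cell are returned unchanged. The correction makes
    the standard log odds ratio defined for sparse tables.
    """
    if all(c > 0 for c in record.cells()):
        return record
    return replace(
        record,
        n_itt_active=record.n_itt_active + 1.0,  # 0.5 to each of drop + complete
        drop_active=record.drop_active + 0.5,
        n_itt_passive=record.n_itt_passive + 1.0,
        drop_passive=record.drop_passive + 0.5,
        corrected=True,
    )


def compute_log_or(record: StudyRecord) -> EffectSize:
    """Standard log odds ratio of dropout (active vs passive) with its variance.

    Requires all four cells positive; apply :func:`continuity_correct` first
    for sparse tables.
    """
    a, b, c, d = record.cells()
    if min(a, b, c, d) <= 0:
        raise UndefinedEffectError(
            f"study {record.study_id!r}: zero cell makes the log odds ratio "
            "undefined; apply continuity_correct first"
        )
    yi = math.log((a / b) / (c / d))
    vi = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectSize(record.study_id, yi, vi, "standard", record.corrected)


def _peto_components(record: StudyRecord) -> tuple[float, float, float]:
    """(O - E, V) ingredients of the Peto log OR for one study."""
    o = record.drop_active
    n1, n2 = record.n_itt_active, record.n_itt_passive
    n = n1 + n2
    events = record.drop_active + record.drop_passive
    e = n1 * events / n
    v = n1 * n2 * events * (n - events) / (n**2 * (n - 1))
    return o, e, v


def compute_peto_log_or(record: StudyRecord) -> EffectSize:
    """Peto approximate log odds ratio (O - E)/V with variance 1/V.

    Defined whenever the study has at least one event and at least one
    non-event overall, so single zero cells need no correction.
    """
    events = record.drop_active + record.drop_passive
    total = record.total_n
    if events <= 0 or events >= total:
        raise UndefinedEffectError(
            f"study {record.study_id!r}: Peto log OR undefined with "
            f"{events:g} events out of {total:g}"
        )
    o, e, v = _peto_components(record)
    return EffectSize(record.study_id, (o - e) / v, 1 / v, "peto", record.corrected)


def compute_effects(
    records: list[StudyRecord],
    method: str = "standard",
    correction: bool = True,
    skip_undefined: bool = False,
) -> list[EffectSize]:
    """Effect sizes for a batch of studies.

    ``method='standard'`` applies the all-cells +0.5 correction to zero-cell
    studies when ``correction`` is true. ``method='peto'`` uses raw counts;
    with ``skip_undefined`` studies with no (or all) events are dropped rather
    than raising.
    """
    out = []
    for rec in records:
        try:
            if method == "standard":
                out.append(compute_log_or(continuity_correct(rec) if correction else rec))
            elif method == "peto":
                out.append(compute_peto_log_or(rec))
            else:
                raise ValueError(f"unknown effect-size method {method!r}")
        except UndefinedEffectError:
            if not skip_undefined:
                raise
    return out


# ---------------------------------------------------------------------------
# random-effects machinery

def _wls(y: np.ndarray, v: np.ndarray, X: np.ndarray, tau2: float):
    """GLS fit under Var_i = v_i + tau2; returns (beta, cov_beta, resid)."""
    w = 1.0 / (v + tau2)
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ y)
    cov = np.linalg.inv(xtwx)
    return beta, cov, y - X @ beta


def _neg_restricted_ll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    beta, _, resid = _wls(y, v, X, tau2)
    _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))


def _tau2_reml(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    hi = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1.0)
    res = optimize.minimize_scalar(
        _neg_restricted_ll,
        bounds=(0.0, hi),
        args=(y, v, X),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    # the bounded optimizer never lands exactly on 0; check the boundary
    if _neg_restricted_ll(0.0, y, v, X) <= res.fun:
        tau2 = 0.0
    return tau2


def _tau2_dl(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments (DerSimonian-Laird) tau2, generalized to moderators."""
    w = 1.0 / v
    Xw = X * w[:, None]
    H = Xw @ np.linalg.solve(X.T @ Xw, X.T)
    P = np.diag(w) - H * w[None, :]  # P = W - W X (X'WX)^-1 X' W
    q = float(y @ P @ y)
    k, p = X.shape
    return max(0.0, (q - (k - p)) / float(np.trace(P)))


def _typical_within_variance(v: np.ndarray) -> float:
    """Higgins-Thompson 'typical' sampling variance s^2 used by I^2."""
    w = 1.0 / v
    return (len(v) - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))


def _qgen(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu) ** 2))


def _tau2_profile_ci(y: np.ndarray, v: np.ndarray, level: float = 0.95):
    """Q-profile confidence interval for tau2 (generalized Q inversion)."""
    k = len(y)
    alpha = 1 - level
    q_hi = stats.chi2.ppf(1 - alpha / 2, k - 1)
    q_lo = stats.chi2.ppf(alpha / 2, k - 1)
    upper_cap = 100.0 * (float(np.var(y)) + float(np.max(v)) + 1.0)

    def solve(target: float) -> float | None:
        f = lambda t: _qgen(t, y, v) - target  # noqa: E731 - decreasing in t
        if f(0.0) <= 0:
            return 0.0
        if f(upper_cap) > 0:
            return None
        return float(optimize.brentq(f, 0.0, upper_cap, xtol=1e-12))

    lo = solve(q_hi)
    hi = solve(q_lo)
    return lo, hi


def pool_random_effects(
    effects: list[EffectSize],
    tau2_estimator: str = "REML",
    label: str | None = None,
) -> PooledEstimate:
    """Inverse-variance random-effects pool of study log odds ratios.

    Weights are 1/(v_i + tau2); the confidence interval is Wald on the log
    scale. I^2 = 100 tau2/(tau2 + s^2) with s^2 the typical within-study
    variance, and its CI comes from the Q-profile interval for tau2.
    """
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    y = np.array([e.yi for e in effects], dtype=float)
    v = np.array([e.vi for e in effects], dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(v > 0)):
        raise ValueError("all effects must have finite yi and positive vi")
    k = len(y)
    X = np.ones((k, 1))
    if k == 1:
        tau2 = 0.0
    elif tau2_estimator.upper() == "REML":
        tau2 = _tau2_reml(y, v, X)
    elif tau2_estimator.upper() == "DL":
        tau2 = _tau2_dl(y, v, X)
    else:
        raise ValueError(f"unknown tau2 estimator {tau2_estimator!r}")

    beta, cov, _ = _wls(y, v, X, tau2)
    mu = float(beta[0])
    se = float(math.sqrt(cov[0, 0]))
    z = mu / se
    p = 2 * stats.norm.sf(abs(z))

    i2 = i2_ci = tau2_ci = None
    if k >= 2:
        s2 = _typical_within_variance(v)
        i2 = 100.0 * tau2 / (tau2 + s2)
        lo, hi = _tau2_profile_ci(y, v)
        if lo is not None and hi is not None:
            tau2_ci = (lo, hi)
            i2_ci = (100.0 * lo / (lo + s2), 100.0 * hi / (hi + s2))
    else:
        i2 = 0.0

    return PooledEstimate(
        mu=mu,
        se=se,
        ci_low=mu - Z975 * se,
        ci_high=mu + Z975 * se,
        tau2=tau2,
        i2=i2,
        k=k,
        p=float(p),
        method=tau2_estimator.upper(),
        i2_ci=i2_ci,
        tau2_ci=tau2_ci,
        label=label,
    )


def pool_peto_fixed(records: list[StudyRecord]) -> PooledEstimate:
    """Classic fixed-effect Peto pool: sum(O - E) / sum(V), SE = 1/sqrt(sum V).

    Studies with zero total events (or all events) carry no information
    (V = 0) and drop out of the sums.
    """
    num = den = 0.0
    k = 0
    for rec in records:
        events = rec.drop_active + rec.drop_passive
        if events <= 0 or events >= rec.total_n:
            continue
        o, e, v = _peto_components(rec)
        num += o - e
        den += v
        k += 1
    if den <= 0:
        raise UndefinedEffectError("no study contributes information to the Peto pool")
    mu = num / den
    se = 1 / math.sqrt(den)
    z = mu / se
    return PooledEstimate(
        mu=mu,
        se=se,
        ci_low=mu - Z975 * se,
        ci_high=mu + Z975 * se,
        tau2=0.0,
        i2=None,
        k=k,
        p=float(2 * stats.norm.sf(abs(z))),
        method="peto-fixed",
    )


def leave_one_out(
    effects: list[EffectSize], tau2_estimator: str = "REML"
) -> list[PooledEstimate]:
    """Re-pool k times, omitting one study each time (influence diagnostic)."""
    if len(effects) < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    out = []
    for i, omitted in enumerate(effects):
        rest = effects[:i] + effects[i + 1 :]
        out.append(
            pool_random_effects(rest, tau2_estimator, label=omitted.study_id)
        )
    return out


def detect_outliers(
    effects: list[EffectSize], pooled: PooledEstimate
) -> list[str]:
    """Studies whose individual 95% CI does not overlap the pooled 95% CI."""
    flagged = []
    for e in effects:
        lo, hi = e.ci()
        if lo > pooled.ci_high or hi < pooled.ci_low:
            flagged.append(e.study_id)
    return flagged


def repool_without(
    effects: list[EffectSize],
    exclude: list[str],
    tau2_estimator: str = "REML",
) -> PooledEstimate:
    """Convenience: pool again with the named studies removed."""
    kept = [e for e in effects if e.study_id not in set(exclude)]
    return pool_random_effects(kept, tau2_estimator, label="outliers removed")


def meta_regress(
    effects: list[EffectSize],
    moderator: np.ndarray,
    moderator_name: str = "moderator",
    tau2_estimator: str = "REML",
) -> MetaRegressionFit:
    """Mixed-effects meta-regression: random study intercept, fixed slope.

    The slope is in log-OR units per unit of the moderator; inference is a
    Wald z-test, consistent with :func:`pool_random_effects`.
    """
    y = np.array([e.yi for e in effects], dtype=float)
    v = np.array([e.vi for e in effects], dtype=float)
    x = np.asarray(moderator, dtype=float)
    if len(x) != len(y):
        raise ValueError("moderator length must equal the number of effects")
    if np.ptp(x) == 0:
        raise ValueError("no moderator variance: moderator is constant")
    X = np.column_stack([np.ones_like(x), x])
    if tau2_estimator.upper() == "REML":
        tau2 = _tau2_reml(y, v, X)
    elif tau2_estimator.upper() == "DL":
        tau2 = _tau2_dl(y, v, X)
    else:
        raise ValueError(f"unknown tau2 estimator {tau2_estimator!r}")
    beta, cov, _ = _wls(y, v, X, tau2)
    b = float(beta[1])
    se = float(math.sqrt(cov[1, 1]))
    z = b / se
    return MetaRegressionFit(
        moderator_name=moderator_name,
        B=b,
        se=se,
        ci_low=b - Z975 * se,
        ci_high=b + Z975 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        intercept=float(beta[0]),
        tau2=tau2,
        k=len(y),
        method=tau2_estimator.upper(),
    )


# ---------------------------------------------------------------------------
# descriptive review


def summarize_review(records: list[StudyRecord]) -> ReviewSummary:
    """Descriptive summary of the reviewed studies.

    Per-arm attrition percentages are computed per study (100*drop/ITT) and
    averaged unweighted across studies. Coded-feature counts are read from the
    records' moderators where present; ``tested_diff``/``detected_diff`` refer
    to whether a study statistically compared (and detected a difference in)
    attrition between arms.
    """
    if not records:
        raise ValueError("no studies to summarize")
    total_n = np.array([r.total_n for r in records], dtype=float)
    att_a = np.array([100.0 * r.drop_active / r.n_itt_active for r in records])
    att_p = np.array([100.0 * r.drop_passive / r.n_itt_passive for r in records])

    def count(key: str) -> int:
        return sum(int(bool(r.moderators.get(key, 0))) for r in records)

    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0  # noqa: E731
    return ReviewSummary(
        n_studies=len(records),
        mean_total_n=float(np.mean(total_n)),
        sd_total_n=sd(total_n),
        mean_attrition_active=float(np.mean(att_a)),
        sd_attrition_active=sd(att_a),
        mean_attrition_passive=float(np.mean(att_p)),
        sd_attrition_passive=sd(att_p),
        n_with_attrition=int(sum(r.drop_active + r.drop_passive > 0 for r in records)),
        n_tested_diff=count("tested_diff"),
        n_detected_diff=count("detected_diff"),
        n_ml_mi=count("used_ml_or_mi"),
    )


def forest_data(effects: list[EffectSize], pooled: PooledEstimate):
    """Forest-plot table: per-study OR, CI, and percent weight.

    Returns a pandas DataFrame; weights are the random-effects weights
    1/(v_i + tau2) normalized to percent.
    """
    import pandas as pd

    v = np.array([e.vi for e in effects])
    w = 1.0 / (v + pooled.tau2)
    w = 100.0 * w / w.sum()
    rows = []
    for e, wi in zip(effects, w):
        lo, hi = e.ci()
        rows.append(
            {
                "study_id": e.study_id,
                "log_or": e.yi,
                "or": e.odds_ratio,
                "ci_low": math.exp(lo),
                "ci_high": math.exp(hi),
                "weight_pct": wi,
            }
        )
    rows.append(
        {
            "study_id": "RE pooled",
            "log_or": pooled.mu,
            "or": pooled.odds_ratio,
            "ci_low": pooled.or_ci[0],
            "ci_high": pooled.or_ci[1],
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
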