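"""Unit and property tests for the differential-attrition meta-analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mnarsens as mn
from mnarsens.meta_attrition import (
    UndefinedEffectError,
    forest_data,
    leave_one_out,
    repool_without,
)

# Reference values computed once with metafor 4.8-0 on the packaged table
# (rma REML/DL, escalc OR add=0.5 to="only0" / PETO add=0), frozen here as an
# independent oracle for the pooling machinery.
METAFOR_STD_REML = dict(mu=0.6634584136, se=0.1319306145, tau2=0.2458842474,
                        i2=53.84954681)
METAFOR_STD_DL = dict(mu=0.6617069382, tau2=0.257576771)
METAFOR_PETO_REML = dict(mu=0.6661671003, se=0.1248886841, tau2=0.2266431483)
METAFOR_METAREG_TOTALN = dict(B=0.002176569002, se=0.000876983464,
                              tau2=0.173121516)


def rec(a_itt, a_drop, p_itt, p_drop, sid="s"):
    return mn.StudyRecord(sid, a_itt, a_drop, p_itt, p_drop)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "a_itt,a_drop,p_itt,p_drop,expected_or",
        [
            (228, 137, 115, 48, 2.10),  # illustrative trial, printed counts
            (10, 5, 10, 5, 1.0),  # identical arms
            (20, 10, 20, 5, 3.0),  # (10/10)/(5/15)
        ],
    )
    def test_log_or_examples(self, a_itt, a_drop, p_itt, p_drop, expected_or):
        es = mn.compute_log_or(rec(a_itt, a_drop, p_itt, p_drop))
        assert es.odds_ratio == pytest.approx(expected_or, abs=0.005)
        # variance is the sum of reciprocal cells
        cells = (a_drop, a_itt - a_drop, p_drop, p_itt - p_drop)
        assert es.vi == pytest.approx(sum(1 / c for c in cells), abs=1e-12)

    def test_log_or_zero_cell_names_study(self):
        with pytest.raises(UndefinedEffectError, match="Enock"):
            mn.compute_log_or(rec(206, 38, 36, 0, sid="Enock et al"))

    def test_peto_balanced_is_zero(self):
        es = mn.compute_peto_log_or(rec(10, 5, 10, 5))
        assert es.yi == pytest.approx(0.0, abs=1e-12)

    def test_peto_illustrative_trial(self):
        es = mn.compute_peto_log_or(rec(228, 137, 115, 48))
        assert es.odds_ratio == pytest.approx(2.09, abs=0.01)

    def test_peto_tolerates_single_zero_cell(self):
        es = mn.compute_peto_log_or(rec(206, 38, 36, 0, sid="Enock et al"))
        assert math.isfinite(es.yi) and es.vi > 0

    def test_peto_undefined_without_events(self):
        with pytest.raises(UndefinedEffectError):
            mn.compute_peto_log_or(rec(20, 0, 18, 0))
        with pytest.raises(UndefinedEffectError):
            mn.compute_peto_log_or(rec(20, 20, 18, 18))

    @pytest.mark.parametrize(
        "cells_in,cells_out",
        [
            ((20, 0, 18, 0), (0.5, 20.5, 0.5, 18.5)),  # zero dropouts both arms
            ((59, 13, 28, 5), (13, 46, 5, 23)),  # clean study unchanged
            ((80, 1, 80, 0), (1.5, 79.5, 0.5, 80.5)),  # single zero cell
        ],
    )
    def test_continuity_correction_rule(self, cells_in, cells_out):
        r = mn.continuity_correct(rec(*cells_in))
        assert r.cells() == pytest.approx(cells_out)

    def test_continuity_correction_flags_only_corrected(self):
        assert mn.continuity_correct(rec(20, 0, 18, 0)).corrected
        assert not mn.continuity_correct(rec(59, 13, 28, 5)).corrected

    def test_peto_close_to_standard_on_balanced_grid(self):
        """On balanced-arm tables with event probabilities in [0.2, 0.8] and
        odds ratios up to 2, the Peto approximation tracks the standard log
        OR to within 0.05 (Peto's known good regime)."""
        for n in (50, 100, 200, 400):
            for pp in np.linspace(0.2, 0.8, 13):
                for or_true in (1.0, 1.25, 1.5, 2.0):
                    odds = pp / (1 - pp) * or_true
                    pa = odds / (1 + odds)
                    if not 0.2 <= pa <= 0.8:
                        continue
                    r = rec(n, n * pa, n, n * pp)
                    diff = abs(mn.compute_log_or(r).yi
                               - mn.compute_peto_log_or(r).yi)
                    assert diff < 0.05

    def test_arm_swap_negates_effect(self, records):
        for r in records[:10]:
            swapped = mn.StudyRecord(
                r.study_id, r.n_itt_passive, r.drop_passive,
                r.n_itt_active, r.drop_active,
            )
            y1 = mn.compute_log_or(mn.continuity_correct(r)).yi
            y2 = mn.compute_log_or(mn.continuity_correct(swapped)).yi
            assert y1 == pytest.approx(-y2, abs=1e-12)


class TestPooling:
    def test_single_study_pool(self):
        es = mn.EffectSize("a", 0.5, 0.04)
        p = mn.pool_random_effects([es])
        assert p.mu == pytest.approx(0.5)
        assert p.tau2 == 0.0
        assert p.ci_low == pytest.approx(0.5 - 1.959964 * 0.2, abs=1e-4)
        assert p.ci_high == pytest.approx(0.5 + 1.959964 * 0.2, abs=1e-4)

    def test_identical_effects_no_heterogeneity(self):
        effs = [mn.EffectSize(str(i), 0.3, 0.05) for i in range(5)]
        p = mn.pool_random_effects(effs)
        assert p.tau2 == pytest.approx(0.0, abs=1e-10)
        assert p.i2 == pytest.approx(0.0, abs=1e-6)
        assert p.mu == pytest.approx(0.3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mn.pool_random_effects([])

    def test_dl_matches_closed_form(self):
        """DL pooling equals an explicit hand-coded computation to 1e-10."""
        y = np.array([0.2, -0.1, 0.4, 0.05, 0.3])
        v = np.array([0.04, 0.09, 0.02, 0.05, 0.03])
        w = 1 / v
        mu_fe = (w * y).sum() / w.sum()
        q = (w * (y - mu_fe) ** 2).sum()
        tau2 = max(0.0, (q - 4) / (w.sum() - (w**2).sum() / w.sum()))
        wr = 1 / (v + tau2)
        mu_re = (wr * y).sum() / wr.sum()
        se_re = 1 / math.sqrt(wr.sum())
        effs = [mn.EffectSize(str(i), yi, vi) for i, (yi, vi) in enumerate(zip(y, v))]
        p = mn.pool_random_effects(effs, "DL")
        assert p.tau2 == pytest.approx(tau2, abs=1e-10)
        assert p.mu == pytest.approx(mu_re, abs=1e-10)
        assert p.se == pytest.approx(se_re, abs=1e-10)

    def test_dl_matches_statsmodels(self):
        """Cross-check DL against statsmodels' meta-analysis pooling."""
        from statsmodels.stats.meta_analysis import combine_effects

        # heterogeneous example so the untruncated statsmodels tau2 is > 0
        y = np.array([0.9, -0.4, 0.6, 0.05, 1.3])
        v = np.array([0.04, 0.09, 0.02, 0.05, 0.03])
        ref = combine_effects(y, v, method_re="chi2")
        effs = [mn.EffectSize(str(i), yi, vi) for i, (yi, vi) in enumerate(zip(y, v))]
        p = mn.pool_random_effects(effs, "DL")
        assert p.mu == pytest.approx(ref.mean_effect_re, abs=1e-10)
        assert p.tau2 == pytest.approx(ref.tau2, abs=1e-10)

    def test_reml_matches_metafor_reference(self, std_effects, peto_effects):
        p = mn.pool_random_effects(std_effects)
        assert p.mu == pytest.approx(METAFOR_STD_REML["mu"], abs=1e-5)
        assert p.se == pytest.approx(METAFOR_STD_REML["se"], abs=1e-5)
        assert p.tau2 == pytest.approx(METAFOR_STD_REML["tau2"], abs=1e-5)
        assert p.i2 == pytest.approx(METAFOR_STD_REML["i2"], abs=1e-3)
        pdl = mn.pool_random_effects(std_effects, "DL")
        assert pdl.mu == pytest.approx(METAFOR_STD_DL["mu"], abs=1e-8)
        assert pdl.tau2 == pytest.approx(METAFOR_STD_DL["tau2"], abs=1e-8)
        pp = mn.pool_random_effects(peto_effects)
        assert pp.mu == pytest.approx(METAFOR_PETO_REML["mu"], abs=1e-5)
        assert pp.tau2 == pytest.approx(METAFOR_PETO_REML["tau2"], abs=1e-5)

    def test_i2_qprofile_interval(self, std_effects):
        """Q-profile I2 interval on the study table (metafor: 19.46-71.09)."""
        p = mn.pool_random_effects(std_effects)
        assert p.i2_ci[0] == pytest.approx(19.4609, abs=0.01)
        assert p.i2_ci[1] == pytest.approx(71.0871, abs=0.01)

    def test_arm_swap_negates_pool(self, records):
        effs = mn.compute_effects(records, "standard", correction=True)
        swapped = [
            mn.compute_log_or(
                mn.continuity_correct(
                    mn.StudyRecord(r.study_id, r.n_itt_passive, r.drop_passive,
                                   r.n_itt_active, r.drop_active)
                )
            )
            for r in records
        ]
        p1 = mn.pool_random_effects(effs)
        p2 = mn.pool_random_effects(swapped)
        assert p1.mu == pytest.approx(-p2.mu, abs=1e-6)
        assert p1.tau2 == pytest.approx(p2.tau2, abs=1e-6)

    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)),
            min_size=2, max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_heterogeneity_bounds(self, pairs):
        effs = [mn.EffectSize(str(i), y, v) for i, (y, v) in enumerate(pairs)]
        for method in ("REML", "DL"):
            p = mn.pool_random_effects(effs, method)
            assert p.tau2 >= 0
            assert 0 <= p.i2 <= 100
            assert p.ci_low <= p.mu <= p.ci_high

    def test_peto_fixed_pool_equals_sum_formula(self, records):
        """Classic Peto pool equals sum(O-E)/sum(V) computed directly."""
        num = den = 0.0
        for r in records:
            ev = r.drop_active + r.drop_passive
            n = r.total_n
            if ev == 0 or ev == n:
                continue
            e = r.n_itt_active * ev / n
            v = r.n_itt_active * r.n_itt_passive * ev * (n - ev) / (n**2 * (n - 1))
            num += r.drop_active - e
            den += v
        p = mn.pool_peto_fixed(records)
        assert p.mu == pytest.approx(num / den, abs=1e-12)
        assert p.se == pytest.approx(1 / math.sqrt(den), abs=1e-12)


class TestDiagnostics:
    def test_leave_one_out_band(self, std_effects):
        """Omitting any single study leaves the pooled OR in a narrow band
        around the full-sample value (published range 1.82-2.10)."""
        loo = leave_one_out(std_effects)
        assert len(loo) == 36
        ors = [e.odds_ratio for e in loo]
        assert 1.80 <= min(ors) and max(ors) <= 2.12
        assert all(e.p < 0.001 for e in loo)

    def test_leave_one_out_two_identical(self):
        effs = [mn.EffectSize("a", 0.4, 0.05), mn.EffectSize("b", 0.4, 0.05)]
        for est in leave_one_out(effs):
            assert est.mu == pytest.approx(0.4)

    def test_leave_one_out_extreme_study_moves_most(self, std_effects):
        effs = std_effects + [mn.EffectSize("extreme", 5.0, 0.01)]
        full = mn.pool_random_effects(effs).mu
        loo = leave_one_out(effs)
        shifts = {e.label: abs(e.mu - full) for e in loo}
        assert max(shifts, key=shifts.get) == "extreme"

    def test_leave_one_out_needs_two(self):
        with pytest.raises(ValueError):
            leave_one_out([mn.EffectSize("a", 0.4, 0.05)])

    def test_outlier_rule_flags_disjoint_ci(self, std_effects):
        pooled = mn.pool_random_effects(std_effects)
        extreme = mn.EffectSize("way-off", pooled.mu + 10, 1e-4)
        flagged = mn.detect_outliers(std_effects + [extreme], pooled)
        assert "way-off" in flagged

    def test_outlier_rule_empty_when_cis_overlap(self):
        effs = [mn.EffectSize(str(i), 0.3, 0.05) for i in range(6)]
        pooled = mn.pool_random_effects(effs)
        assert mn.detect_outliers(effs, pooled) == []

    def test_fixture_outliers(self, std_effects):
        pooled = mn.pool_random_effects(std_effects)
        flagged = mn.detect_outliers(std_effects, pooled)
        assert sorted(flagged) == [
            "Kristjansdottir et al", "Oh et al", "Proudfoot et al",
            "van Emmerik et al",
        ]
        rp = repool_without(std_effects, flagged)
        assert rp.k == 32

    def test_forest_data_weights(self, std_effects):
        pooled = mn.pool_random_effects(std_effects)
        df = forest_data(std_effects, pooled)
        assert len(df) == 37
        assert df["weight_pct"][:-1].sum() == pytest.approx(100.0)


class TestMetaRegression:
    def test_matches_metafor_reference(self, records, std_effects):
        x = np.array([r.moderators["total_n"] for r in records])
        fit = mn.meta_regress(std_effects, x, "total_n")
        assert fit.B == pytest.approx(METAFOR_METAREG_TOTALN["B"], abs=1e-7)
        assert fit.se == pytest.approx(METAFOR_METAREG_TOTALN["se"], abs=1e-7)
        assert fit.tau2 == pytest.approx(METAFOR_METAREG_TOTALN["tau2"], abs=1e-5)

    def test_constant_moderator_rejected(self, std_effects):
        with pytest.raises(ValueError, match="moderator"):
            mn.meta_regress(std_effects, np.ones(len(std_effects)))

    def test_centered_moderator_intercept_near_pool(self, std_effects):
        """With a centered moderator the intercept estimates the average
        effect, close to the intercept-only pooled value."""
        x = np.array([e.vi for e in std_effects])
        fit = mn.meta_regress(std_effects, x - x.mean(), "centered")
        pooled = mn.pool_random_effects(std_effects)
        assert fit.intercept == pytest.approx(pooled.mu, abs=0.05)

    def test_slope_recovery_coverage(self):
        """The 95% CI covers a known simulated slope in >=90% of replicates."""
        rng = np.random.default_rng(42)
        true_b = 0.05
        k, n_rep = 30, 300
        covered = 0
        for _ in range(n_rep):
            x = rng.uniform(0, 10, k)
            v = rng.uniform(0.01, 0.1, k)
            y = 0.2 + true_b * x + rng.normal(0, np.sqrt(v + 0.04))
            effs = [mn.EffectSize(str(i), y[i], v[i]) for i in range(k)]
            fit = mn.meta_regress(effs, x)
            covered += fit.ci_low <= true_b <= fit.ci_high
        assert covered / n_rep >= 0.90


class TestReviewSummary:
    def test_fixture_summary(self, records):
        rs = mn.summarize_review(records)
        assert rs.n_studies == 36
        assert rs.n_ml_mi == 18
        assert rs.n_tested_diff == 11
        assert rs.n_detected_diff == 6
        assert rs.mean_total_n == pytest.approx(143.47, abs=0.01)
        assert rs.sd_total_n == pytest.approx(118.65, abs=0.01)

    def test_single_study_attrition(self):
        rs = mn.summarize_review([rec(100, 25, 100, 25)])
        assert rs.mean_attrition_active == pytest.approx(25.0)
        assert rs.mean_attrition_passive == pytest.approx(25.0)
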