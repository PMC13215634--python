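"""CCC, limits of agreement, bootstrap machinery and level panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bracewear.agreement import (
    agreement_at_level,
    band,
    bland_altman_loa,
    build_panel,
    ccc_ci,
    cluster_bootstrap_ci,
    lin_ccc,
    rm_corrected_sd,
    vc_ccc,
)
from bracewear.types import DailyWearSeries, DegenerateInputError, InputError


def moment_ccc_oracle(x, y):
    """Independent hand-coded evaluation of the concordance moment formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * sxy / (vx + vy + (mx - my) ** 2)


finite_vec = st.lists(
    st.floats(min_value=-500, max_value=500, allow_nan=False), min_size=3, max_size=40
)


class TestLinCCC:
    def test_shifted_sequence_frozen_value(self):
        expected = moment_ccc_oracle([1, 2, 3, 4], [2, 3, 4, 5])
        assert expected == pytest.approx(0.714286, abs=1e-6)
        assert lin_ccc([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(expected, abs=1e-12)

    def test_matches_moment_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(50, 20, rng.integers(3, 30))
            y = x * rng.uniform(0.5, 1.5) + rng.normal(0, 10, len(x))
            assert lin_ccc(x, y) == pytest.approx(moment_ccc_oracle(x, y), abs=1e-9)

    def test_perfect_concordance_is_exactly_one(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.normal(0, 1, 20)
            assert lin_ccc(x, x) == 1.0

    def test_independent_normals_have_near_zero_ccc(self):
        rng = np.random.default_rng(3)
        assert abs(lin_ccc(rng.normal(0, 1, 10**5), rng.normal(0, 1, 10**5))) < 0.02

    def test_both_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            lin_ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            lin_ccc([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(finite_vec, st.randoms(use_true_random=False))
    def test_bounded_by_pearson_and_symmetric(self, x, rnd):
        y = [v + rnd.uniform(-100, 100) for v in x]
        x, y = np.asarray(x), np.asarray(y)
        if x.var() == 0 and y.var() == 0:
            return
        c = lin_ccc(x, y)
        assert -1 - 1e-9 <= c <= 1 + 1e-9
        assert lin_ccc(y, x) == pytest.approx(c, abs=1e-12)
        if x.var() > 0 and y.var() > 0:
            r = np.corrcoef(x, y)[0, 1]
            assert abs(c) <= abs(r) + 1e-9


class TestCCCConfidenceInterval:
    def test_closed_form(self):
        lo, hi = ccc_ci(0.9, 10)
        half = 1.96 / np.sqrt(8)
        assert lo == pytest.approx(np.tanh(np.arctanh(0.9) - half), abs=1e-9)
        assert hi == pytest.approx(np.tanh(np.arctanh(0.9) + half), abs=1e-9)

    def test_symmetric_about_zero(self):
        lo, hi = ccc_ci(0.0, 500)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_boundary_ccc_gives_point_interval_with_warning(self):
        with pytest.warns(UserWarning):
            assert ccc_ci(1.0, 10) == (1.0, 1.0)

    def test_nominal_coverage_on_bivariate_normal(self):
        # equal means and variances: true CCC = rho = 0.5
        rng = np.random.default_rng(7)
        rho, n, reps = 0.5, 50, 2000
        cov = [[1, rho], [rho, 1]]
        hits = 0
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            c = lin_ccc(xy[:, 0], xy[:, 1])
            lo, hi = ccc_ci(c, n)
            hits += lo <= rho <= hi
        assert 0.93 <= hits / reps <= 0.97


class TestBlandAltman:
    def test_constant_differences_give_zero_width(self):
        assert bland_altman_loa([4.0, 4.0, 4.0]) == (4.0, 4.0, 4.0)

    def test_frozen_example(self):
        bias, lo, hi = bland_altman_loa([-10.0, 0.0, 10.0])
        assert (bias, lo, hi) == pytest.approx((0.0, -19.6, 19.6))

    def test_large_sample_normal_calibration(self):
        rng = np.random.default_rng(11)
        sigma = 37.0
        bias, lo, hi = bland_altman_loa(rng.normal(0, sigma, 10**4))
        assert (hi - lo) / 2 == pytest.approx(1.96 * sigma, rel=0.03)

    def test_antisymmetric_under_argument_swap(self):
        rng = np.random.default_rng(12)
        d = rng.normal(5, 2, 50)
        b1, lo1, hi1 = bland_altman_loa(d)
        b2, lo2, hi2 = bland_altman_loa(-d)
        assert b2 == pytest.approx(-b1) and lo2 == pytest.approx(-hi1) and hi2 == pytest.approx(-lo1)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            bland_altman_loa([1.0])


class TestRepeatedMeasuresSD:
    def test_reduces_to_sample_sd_with_one_obs_per_subject(self):
        d = np.array([1.0, 4.0, -2.0, 3.0])
        got = rm_corrected_sd(d, ["a", "b", "c", "d"])
        assert got == pytest.approx(np.std(d, ddof=1), abs=1e-12)

    def test_exceeds_naive_sd_under_strong_subject_effects(self):
        rng = np.random.default_rng(13)
        subj = np.repeat(np.arange(5), 50)
        d = np.repeat(rng.normal(0, 30, 5), 50) + rng.normal(0, 5, 250)
        assert rm_corrected_sd(d, subj) >= np.std(d, ddof=1)


class TestClusterBootstrap:
    @staticmethod
    def _panel(x, y, subj):
        return pd.DataFrame({"participant_id": subj, "sensor": x, "selfreport": y})

    def test_identical_sources_give_degenerate_unit_interval(self):
        x = np.tile(np.arange(10.0), 4)
        panel = self._panel(x, x, np.repeat(list("abcd"), 10))
        assert cluster_bootstrap_ci(panel, lin_ccc, n_boot=200, seed=0) == (1.0, 1.0)

    def test_single_participant_rejected(self):
        panel = self._panel([1.0, 2.0], [1.0, 2.0], ["a", "a"])
        with pytest.raises(InputError):
            cluster_bootstrap_ci(panel, lin_ccc, n_boot=200, seed=0)

    def test_too_few_resamples_rejected(self):
        panel = self._panel([1.0, 2.0], [1.0, 2.0], ["a", "b"])
        with pytest.raises(InputError):
            cluster_bootstrap_ci(panel, lin_ccc, n_boot=50, seed=0)

    def test_seeded_and_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(60, 20, 80)
        panel = self._panel(x, x + rng.normal(0, 10, 80), np.repeat(np.arange(8), 10))
        a = cluster_bootstrap_ci(panel, lin_ccc, n_boot=300, seed=42)
        b = cluster_bootstrap_ci(panel, lin_ccc, n_boot=300, seed=42)
        assert a == b


class TestBanding:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.70, "moderate"),
            (0.92, "excellent"),
            (0.5, "moderate"),
            (0.75, "moderate"),
            (0.9, "strong"),
            (0.49, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, value, label):
        assert band(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            band(1.2)


def _cohort_dailies(seed=0, n_subj=6, n_days=21, noise=25.0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2024-01-01", periods=n_days, freq="D")
    sensor, report = {}, {}
    for i in range(n_subj):
        pid = f"P{i:02d}"
        base = rng.uniform(20, 120)
        x = np.clip(rng.normal(base, 30, n_days), 0, 1440)
        y = np.clip(x + rng.normal(0, noise, n_days), 0, 1440)
        sensor[pid] = DailyWearSeries(pid, pd.Series(x, index=idx))
        report[pid] = DailyWearSeries(pid, pd.Series(y, index=idx))
    return sensor, report


class TestLevels:
    def test_aggregated_ccc_equals_ccc_of_summary_vectors(self):
        from bracewear.aggregate import summarize

        sensor, report = _cohort_dailies()
        est = agreement_at_level(sensor, report, "avg_daily", compute_ci=False)
        x = [summarize(sensor[p]).avg_daily_minutes for p in sorted(sensor)]
        y = [summarize(report[p]).avg_daily_minutes for p in sorted(report)]
        assert est.ccc == lin_ccc(x, y)

    def test_unknown_level_rejected(self):
        sensor, report = _cohort_dailies()
        with pytest.raises(InputError):
            build_panel(sensor, report, "weekly")

    def test_daily_panel_drops_missing_pairs(self):
        sensor, report = _cohort_dailies(n_subj=3)
        r = report["P00"].minutes.copy()
        r.iloc[2:5] = np.nan
        report["P00"] = DailyWearSeries("P00", r)
        panel = build_panel(sensor, report, "daily")
        assert len(panel) == 3 * 21 - 3
        assert panel[["sensor", "selfreport"]].notna().all().all()

    def test_rolling_level_pairs_shrink_with_window(self):
        sensor, report = _cohort_dailies()
        daily = build_panel(sensor, report, "daily")
        r3 = build_panel(sensor, report, "rolling3")
        r7 = build_panel(sensor, report, "rolling7")
        assert len(daily) > len(r3) > len(r7)

    def test_estimate_invariants(self):
        sensor, report = _cohort_dailies()
        est = agreement_at_level(sensor, report, "daily", n_boot=300, seed=1)
        assert est.loa[0] <= est.bias <= est.loa[1]
        assert -1 <= est.ccc <= 1
        assert est.band == band(est.ccc)
        assert est.n_participants == 6

    def test_no_shared_participants_rejected(self):
        sensor, _ = _cohort_dailies()
        _, report = _cohort_dailies()
        report = {f"X{p}": s for p, s in report.items()}
        with pytest.raises(InputError):
            build_panel(sensor, report, "daily")

    def test_variance_components_ccc_recovers_known_value(self):
        # both methods share a subject intercept a_i ~ N(0, 40^2) plus
        # independent N(0, 20^2) residuals and no method shift, so the
        # estimator's target is va / (va + ve) = 1600/2000 = 0.8
        rng = np.random.default_rng(21)
        n_subj, n_days = 30, 40
        a = rng.normal(0, 40, n_subj)
        idx = pd.date_range("2024-01-01", periods=n_days, freq="D")
        sensor, report = {}, {}
        for i in range(n_subj):
            pid = f"P{i:02d}"
            x = 200 + a[i] + rng.normal(0, 20, n_days)
            y = 200 + a[i] + rng.normal(0, 20, n_days)
            sensor[pid] = DailyWearSeries(pid, pd.Series(np.clip(x, 0, 1440), index=idx))
            report[pid] = DailyWearSeries(pid, pd.Series(np.clip(y, 0, 1440), index=idx))
        panel = build_panel(sensor, report, "daily")
        true = 1600 / (1600 + 400)
        assert vc_ccc(panel) == pytest.approx(true, abs=0.1)
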