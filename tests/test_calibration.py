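"""Calibration fitting, R² trajectory, LOD, and the metric-concordance screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import ols_normal_equations
from kinelisa import calibration as cal
from kinelisa.errors import DomainError, FitError
from kinelisa.kinetics import KineticTrace

STANDARDS = {"b": 0.0, "s1": 1.0, "s10": 10.0, "s100": 100.0, "s1000": 1000.0}

# replicate-chip optical densities used for the concordance screen
CHIP_ODS = {"A": 5.071, "B": 4.984, "C": 4.528, "D": 5.056, "E": 5.011}


class TestCoefficientOfVariation:
    def test_replicate_od_concordance_below_two_percent(self):
        cv = cal.coefficient_of_variation([5.071, 4.984, 5.056, 5.011])
        assert cv == pytest.approx(0.0080, abs=1e-4)
        assert cv < 0.02

    def test_identical_values_give_zero(self):
        assert cal.coefficient_of_variation([3.3, 3.3, 3.3]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sample_sd(self):
        assert cal.coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            cal.coefficient_of_variation([1.0])
        with pytest.raises(DomainError):
            cal.coefficient_of_variation([-1.0, 1.0])


class TestFitCalibration:
    def test_exact_log_linear_signals_recovered(self):
        signals = {cid: 2.0 - 0.3 * np.log10(c) for cid, c in STANDARDS.items() if c > 0}
        model = cal.fit_calibration(STANDARDS, signals, t_read=100.0)
        assert model.slope == pytest.approx(-0.3, abs=1e-12)
        assert model.intercept == pytest.approx(2.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.n_points == 4  # blank excluded

    def test_constant_signals_flagged_degenerate(self):
        signals = {cid: 1.0 for cid, c in STANDARDS.items() if c > 0}
        model = cal.fit_calibration(STANDARDS, signals, t_read=0.0)
        assert model.degenerate and model.r_squared is None

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            concs = 10.0 ** rng.uniform(-1, 4, size=rng.integers(3, 8))
            concs = np.unique(concs)
            if len(concs) < 3:
                continue
            standards = {f"s{i}": c for i, c in enumerate(concs)}
            signals = {f"s{i}": rng.normal() for i in range(len(concs))}
            model = cal.fit_calibration(standards, signals, t_read=0.0)
            slope, intercept, r2 = ols_normal_equations(
                np.log10(concs), [signals[f"s{i}"] for i in range(len(concs))]
            )
            assert model.slope == pytest.approx(slope, abs=1e-10)
            assert model.intercept == pytest.approx(intercept, abs=1e-10)
            assert model.r_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_standards_rejected(self):
        with pytest.raises(FitError):
            cal.fit_calibration({"a": 1.0, "b": 10.0}, {"a": 1.0, "b": 2.0}, t_read=0.0)

    def test_missing_signal_rejected(self):
        with pytest.raises(FitError, match="s1000"):
            cal.fit_calibration(STANDARDS, {"s1": 1.0, "s10": 2.0, "s100": 3.0}, t_read=0.0)

    def test_r_squared_invariant_under_affine_signal_transform(self):
        rng = np.random.default_rng(9)
        signals = {cid: 1.0 - 0.2 * np.log10(c) + rng.normal(0, 0.05) for cid, c in STANDARDS.items() if c > 0}
        base = cal.fit_calibration(STANDARDS, signals, t_read=0.0)
        mapped = {cid: 3.0 * v + 7.0 for cid, v in signals.items()}
        scaled = cal.fit_calibration(STANDARDS, mapped, t_read=0.0)
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)
        assert scaled.slope == pytest.approx(3.0 * base.slope, abs=1e-12)


def _trace(cid, times, values):
    return KineticTrace(cid, np.asarray(times, float), np.asarray(values, float), np.zeros(len(values), bool))


class TestR2Trajectory:
    def test_single_grid_point_matches_direct_fit(self):
        times = [0.0, 50.0, 100.0]
        offsets = {"s1": 0.011, "s10": -0.007, "s100": 0.002, "s1000": -0.013}
        traces = {
            cid: _trace(cid, times, 1.0 - 0.1 * np.log10(c) * np.array([0.0, 0.5, 1.0]) + offsets[cid])
            for cid, c in STANDARDS.items()
            if c > 0
        }
        traj = cal.r2_trajectory(traces, STANDARDS, [50.0])
        signals = {cid: np.interp(50.0, times, tr.values) for cid, tr in traces.items()}
        model = cal.fit_calibration(STANDARDS, signals, t_read=50.0)
        assert len(traj) == 1
        assert traj["r_squared"].iloc[0] == pytest.approx(model.r_squared)

    def test_identical_traces_yield_nan_everywhere(self):
        times = [0.0, 10.0, 20.0]
        traces = {cid: _trace(cid, times, [1.0, 1.0, 1.0]) for cid, c in STANDARDS.items() if c > 0}
        traj = cal.r2_trajectory(traces, STANDARDS, [0.0, 10.0, 20.0])
        assert traj["r_squared"].isna().all()

    def test_growing_separation_gives_increasing_r2(self):
        # signal separation proportional to t, with fixed per-chamber offsets:
        # the offset noise dominates early and washes out as separation grows
        rng = np.random.default_rng(21)
        times = np.linspace(0.0, 100.0, 11)
        traces = {}
        for cid, c in STANDARDS.items():
            if c > 0:
                offset = rng.normal(0, 0.03)
                traces[cid] = _trace(cid, times, offset + np.log10(c) * times / 100.0)
        traj = cal.r2_trajectory(traces, STANDARDS, times[1:])
        r2 = traj["r_squared"].to_numpy()
        assert np.all(np.diff(r2) >= -1e-12)
        assert r2[-1] > 0.99


class TestEarliestReliableTime:
    def test_first_sustained_crossing(self):
        series = pd.DataFrame({"time_s": [25, 50, 75, 100], "r_squared": [0.4, 0.8, 0.96, 0.97]})
        assert cal.earliest_reliable_time(series) == 75.0

    def test_never_crossing_returns_none(self):
        series = pd.DataFrame({"time_s": [0, 10], "r_squared": [0.5, 0.9]})
        assert cal.earliest_reliable_time(series) is None

    def test_single_point_crossing_not_sustained(self):
        series = pd.DataFrame({"time_s": [0, 10, 20, 30], "r_squared": [0.96, 0.90, 0.97, 0.98]})
        assert cal.earliest_reliable_time(series) == 20.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        r2 = np.clip(np.sort(rng.random(20)) + rng.normal(0, 0.05, 20), 0, 1)
        series = pd.DataFrame({"time_s": np.arange(20.0), "r_squared": r2})
        prev = -np.inf
        for thr in [0.2, 0.5, 0.8, 0.9, 0.99]:
            t = cal.earliest_reliable_time(series, threshold=thr)
            t = np.inf if t is None else t
            assert t >= prev
            prev = t


class TestEstimateLod:
    model = cal.CalibrationModel(t_read=600.0, slope=-0.12, intercept=1.02, r_squared=0.99)

    def test_zero_blank_sd_inverts_blank_mean(self):
        est = cal.estimate_lod(self.model, [1.0, 1.0])
        assert est.blank_sd == 0.0
        assert est.lod == pytest.approx(self.model.invert(1.0), rel=1e-12)

    def test_matches_closed_form_inversion(self):
        blanks = [0.995, 1.003, 0.999]
        est = cal.estimate_lod(self.model, blanks, k=3.0)
        mean, sd = np.mean(blanks), np.std(blanks, ddof=1)
        expected = 10.0 ** (((mean - 3.0 * sd) - 1.02) / -0.12)
        assert est.lod == pytest.approx(expected, rel=1e-9)

    def test_larger_blank_sd_worsens_lod_for_decreasing_signal(self):
        tight = cal.estimate_lod(self.model, [1.0, 1.002])
        loose = cal.estimate_lod(self.model, [0.99, 1.012])
        assert loose.lod > tight.lod

    def test_shift_direction_follows_slope_sign(self):
        rising = cal.CalibrationModel(t_read=0.0, slope=0.12, intercept=0.1, r_squared=0.99)
        est = cal.estimate_lod(rising, [0.2, 0.22])
        assert est.lod == pytest.approx(rising.invert(0.21 + 3 * est.blank_sd), rel=1e-9)

    def test_flat_curve_rejected(self):
        flat = cal.CalibrationModel(t_read=0.0, slope=0.0, intercept=1.0, r_squared=None, degenerate=True)
        with pytest.raises(FitError):
            cal.estimate_lod(flat, [1.0, 1.0])

    def test_needs_two_blanks(self):
        with pytest.raises(DomainError):
            cal.estimate_lod(self.model, [1.0])


class TestCompareMetrics:
    def test_scaled_copy_of_reference_passes(self):
        metric = {cid: 0.2 * od for cid, od in CHIP_ODS.items()}
        (report,) = cal.compare_metrics({"m": metric}, CHIP_ODS)
        assert report.passes and report.cv < 0.02 and report.trend_concordant

    def test_discordant_ranking_fails_trend(self):
        # make chip A (a concordant chip) the extreme one in the metric
        metric = dict(CHIP_ODS)
        metric["A"] = 20.0
        (report,) = cal.compare_metrics({"m": metric}, CHIP_ODS)
        assert report.evaluable and not report.trend_concordant and not report.passes

    def test_noisy_concordant_values_fail_cv(self):
        metric = {"A": 5.0, "B": 6.0, "C": 4.5, "D": 5.5, "E": 5.2}
        (report,) = cal.compare_metrics({"m": metric}, CHIP_ODS)
        assert report.evaluable and not report.cv_ok and not report.passes

    def test_missing_chip_not_evaluable(self):
        metric = {cid: od for cid, od in CHIP_ODS.items() if cid != "D"}
        (report,) = cal.compare_metrics({"m": metric}, CHIP_ODS)
        assert not report.evaluable and not report.passes

    def test_trend_match_rate_under_permuted_metrics(self):
        # assigning the value set {5.0, 5.1, 5.2, 5.3, 9.0} to the chips in every
        # order: the trend flag passes exactly when 9.0 lands on the OD-extreme chip
        values = [5.0, 5.1, 5.2, 5.3, 9.0]
        chips = list(CHIP_ODS)
        hits = 0
        for perm in itertools.permutations(values):
            metric = dict(zip(chips, perm))
            (report,) = cal.compare_metrics({"m": metric}, CHIP_ODS)
            hits += report.trend_concordant
        assert hits == 24  # 4! of 5! permutations, i.e. a 1/5 chance for a random metric
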