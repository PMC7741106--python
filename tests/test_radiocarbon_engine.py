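import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paleoproxy import growth_rates as gr
from paleoproxy import radiocarbon_engine as rc
from paleoproxy import synthetic_population as sp


class _ZeroNoiseRng:
    """Generator stand-in whose gaussian perturbations are exactly zero."""

    def __init__(self, u: float = 0.5):
        self._u = u

    def random(self, size=None):
        return np.full(size, self._u) if size is not None else self._u

    def normal(self, loc=0.0, scale=1.0, size=None):
        return np.zeros(size) if size is not None else 0.0


CURVE_FILE = """\
# fixture calibration curve
# CAL BP, 14C age, Error, Delta 14C, Sigma
300,350,12,0.0,0.0
200,240,11,0.0,0.0
100,120,10,0.0,0.0
"""


class TestCurveIO:
    def test_read_fixture(self, tmp_path):
        path = tmp_path / "fixture.14c"
        path.write_text(CURVE_FILE)
        curve = rc.read_calibration_curve(path)
        assert len(curve) == 3
        np.testing.assert_array_equal(curve.cal_bp, [100, 200, 300])
        np.testing.assert_array_equal(curve.c14_age, [120, 240, 350])
        np.testing.assert_array_equal(curve.curve_error, [10, 11, 12])

    def test_descending_input_stored_ascending(self, tmp_path):
        path = tmp_path / "fixture.14c"
        path.write_text(CURVE_FILE)
        curve = rc.read_calibration_curve(path)
        assert np.all(np.diff(curve.cal_bp) > 0)

    def test_wrong_field_count_names_row(self, tmp_path):
        path = tmp_path / "bad.14c"
        path.write_text("100,120,10,0.0,0.0\n200,240,11,0.0\n")
        with pytest.raises(rc.CalibrationError, match="line 2"):
            rc.read_calibration_curve(path)

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "bad.14c"
        path.write_text("100,120,10\n200,abc,11\n")
        with pytest.raises(rc.CalibrationError, match="line 2"):
            rc.read_calibration_curve(path)

    def test_identity_curve(self):
        curve = rc.make_identity_curve(4_000, 6_000)
        assert len(curve) == 2_001
        assert curve.mu(5_000) == 5_000
        assert np.all(curve.curve_error == 0)

    def test_wiggly_curve_deterministic(self):
        a = rc.make_wiggly_curve(4_000, 6_000, seed=7)
        b = rc.make_wiggly_curve(4_000, 6_000, seed=7)
        np.testing.assert_array_equal(a.c14_age, b.c14_age)
        assert np.std(a.c14_age - a.cal_bp) == pytest.approx(20.0, rel=1e-6)


class TestErrorModel:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            rc.ErrorModel(lower=80, upper=20)

    def test_draws_within_truncation(self):
        draws = rc.ErrorModel().sample(np.random.default_rng(0), 100_000)
        assert draws.min() >= 20.0
        assert draws.max() <= 80.0

    def test_mean_near_mu(self):
        draws = rc.ErrorModel().sample(np.random.default_rng(1), 100_000)
        assert draws.mean() == pytest.approx(50.0, abs=0.2)


class TestCalibrate:
    def test_identity_curve_gives_discretized_normal(self, identity_curve):
        dens = rc.calibrate(rc.RadiocarbonDate(5_000, 50), identity_curve)
        assert dens.mode() == 5_000
        expect = stats.norm.pdf((dens.cal_bp - 5_000) / 50.0)
        expect = expect / expect.sum()
        np.testing.assert_allclose(dens.pmf, expect, atol=1e-12)

    def test_mass_sums_to_one(self, identity_curve):
        dens = rc.calibrate(rc.RadiocarbonDate(7_123, 35), identity_curve)
        assert dens.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_central_interval_matches_normal_quantiles(self, identity_curve):
        dens = rc.calibrate(rc.RadiocarbonDate(5_000, 50), identity_curve)
        lo, hi = dens.interval(0.9545)
        assert abs(lo - 4_900) <= 2
        assert abs(hi - 5_100) <= 2

    def test_date_outside_curve_rejected(self, identity_curve):
        with pytest.raises(rc.CalibrationError, match="outside"):
            rc.calibrate(rc.RadiocarbonDate(40_000, 30), identity_curve)


class TestUncalibrate:
    def test_zero_noise_round_trip(self, identity_curve):
        date = rc.uncalibrate(5_000, identity_curve, seed=_ZeroNoiseRng())
        assert date.c14_age == 5_000

    def test_lab_errors_within_truncation(self, identity_curve):
        ages, errs = rc.uncalibrate_many(
            np.full(10_000, 5_000.0), identity_curve, seed=3
        )
        assert errs.min() >= 20.0
        assert errs.max() <= 80.0

    def test_outside_curve_rejected(self, identity_curve):
        with pytest.raises(rc.CalibrationError, match="outside"):
            rc.uncalibrate(100.0, identity_curve, seed=0)

    def test_round_trip_mode_on_grid(self, identity_curve):
        """calibrate(uncalibrate(theta)) peaks at theta when noise is off."""
        for theta in (4_500, 6_000, 9_999):
            date = rc.uncalibrate(theta, identity_curve, seed=_ZeroNoiseRng())
            dens = rc.calibrate(date, identity_curve)
            assert abs(dens.mode() - theta) <= 1


class TestSampleCalendarDates:
    def _traj(self, sizes):
        years = np.arange(len(sizes) + 999, 999, -1)
        return sp.PopulationTrajectory(years, np.asarray(sizes, dtype=float))

    def test_flat_weights_uniform(self):
        traj = self._traj(np.ones(50))
        draws = rc.sample_calendar_dates(traj, 100_000, (1_049, 1_000), seed=0)
        counts = np.bincount(draws - 1_000, minlength=50)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_point_mass(self):
        sizes = np.zeros(50)
        sizes[20] = 3.0
        traj = self._traj(sizes)
        draws = rc.sample_calendar_dates(traj, 1_000, (1_049, 1_000), seed=1)
        assert np.all(draws == traj.years[20])

    def test_weight_ratio(self):
        """Weights 1:3 -> draw fractions 0.25/0.75 within binomial error."""
        sizes = np.concatenate([np.ones(25), np.full(25, 3.0)])
        traj = self._traj(sizes)
        draws = rc.sample_calendar_dates(traj, 40_000, (1_049, 1_000), seed=2)
        frac_heavy = np.mean(draws <= traj.years[25])
        # 5 sigma: sqrt(0.75*0.25/40000) ~ 0.00217
        assert abs(frac_heavy - 0.75) < 0.011

    def test_all_zero_weights_rejected(self):
        traj = self._traj(np.zeros(50))
        with pytest.raises(ValueError, match="zero"):
            rc.sample_calendar_dates(traj, 10, (1_049, 1_000), seed=0)

    def test_bad_range_rejected(self):
        traj = self._traj(np.ones(50))
        with pytest.raises(ValueError):
            rc.sample_calendar_dates(traj, 10, (1_000, 1_049), seed=0)


class TestBuildSpd:
    def test_identical_dates_equal_single_density(self, identity_curve):
        date = rc.RadiocarbonDate(5_000, 40)
        spd = rc.build_spd([date] * 7, identity_curve)
        dens = rc.calibrate(date, identity_curve)
        on_support = np.isin(spd.cal_bp, dens.cal_bp)
        np.testing.assert_allclose(spd.probability[on_support], dens.pmf, atol=1e-12)

    def test_normalized_sum(self, identity_curve):
        dates = [rc.RadiocarbonDate(5_000, 40), rc.RadiocarbonDate(7_000, 60)]
        spd = rc.build_spd(dates, identity_curve)
        assert spd.probability.sum() == pytest.approx(1.0, abs=1e-9)

    def test_raw_mode_sums_to_n_dates(self, identity_curve):
        dates = [rc.RadiocarbonDate(5_000, 40), rc.RadiocarbonDate(7_000, 60)]
        spd = rc.build_spd(dates, identity_curve, normalize=False)
        assert spd.probability.sum() == pytest.approx(2.0, abs=1e-9)

    def test_two_separated_dates_bimodal(self, identity_curve):
        dates = [rc.RadiocarbonDate(5_000, 40), rc.RadiocarbonDate(8_000, 40)]
        spd = rc.build_spd(dates, identity_curve)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(spd.probability, prominence=spd.probability.max() / 4)
        assert sorted(spd.cal_bp[peaks]) == [5_000, 8_000]

    def test_empty_rejected(self, identity_curve):
        with pytest.raises(rc.CalibrationError, match="empty"):
            rc.build_spd([], identity_curve)

    def test_spd_csv_round_trip(self, identity_curve, tmp_path):
        spd = rc.build_spd([rc.RadiocarbonDate(5_000, 40)], identity_curve)
        path = tmp_path / "spd.csv"
        spd.to_csv(path)
        back = rc.SPD.from_csv(path)
        np.testing.assert_allclose(back.probability, spd.probability)
        assert back.normalized


class TestTaphonomicCorrection:
    def _uniform_spd(self):
        grid = np.arange(1_000, 2_001, dtype=float)
        return rc.SPD(grid, np.full(grid.size, 1.0 / grid.size), n_dates=1)

    def test_constant_survival_is_identity(self):
        spd = self._uniform_spd()
        out = rc.taphonomic_correction(spd, exponent=0.0)
        np.testing.assert_allclose(out.probability, spd.probability, atol=1e-15)

    def test_uniform_spd_becomes_increasing_with_age(self):
        out = rc.taphonomic_correction(self._uniform_spd())
        assert np.all(np.diff(out.probability) > 0)  # grid ascends in cal BP

    def test_growth_rate_lower_after_correction(self):
        """Correction inflates old mass, so fitted growth toward present drops."""
        grid = np.arange(1_000, 5_001, dtype=float)
        prob = np.exp(-0.001 * grid)
        spd = rc.SPD(grid, prob / prob.sum(), n_dates=1)
        corrected = rc.taphonomic_correction(spd)
        before = gr.fit_exponential(grid, spd.probability, bp=True).rate
        after = gr.fit_exponential(grid, corrected.probability, bp=True).rate
        assert after < before

    def test_nonpositive_survival_rejected(self):
        spd = self._uniform_spd()
        with pytest.raises(rc.CalibrationError, match="positive"):
            rc.taphonomic_correction(spd, offset=-3_000.0)


class TestForwardSimulateSpd:
    def test_composition_matches_pipeline(self, default_truth, identity_curve):
        spd = rc.forward_simulate_spd(
            default_truth, 200, (10_000, 5_881), identity_curve, seed=9
        )
        rng = np.random.default_rng(9)
        years = rc.sample_calendar_dates(default_truth, 200, (10_000, 5_881), rng)
        ages, errs = rc.uncalibrate_many(years.astype(float), identity_curve, seed=rng)
        manual = rc.build_spd(list(zip(ages, errs)), identity_curve)
        np.testing.assert_allclose(spd.probability, manual.probability, atol=1e-15)

    def test_full_scale_run_completes(self, default_truth, identity_curve):
        spd = rc.forward_simulate_spd(
            default_truth, 5_000, (10_000, 5_881), identity_curve, seed=1
        )
        assert spd.n_dates == 5_000
        assert spd.probability.sum() == pytest.approx(1.0, abs=1e-9)

    def test_different_seeds_differ(self, default_truth, identity_curve):
        a = rc.forward_simulate_spd(default_truth, 300, (10_000, 5_881), identity_curve, seed=1)
        b = rc.forward_simulate_spd(default_truth, 300, (10_000, 5_881), identity_curve, seed=2)
        assert np.max(np.abs(a.probability - b.probability)) > 0

    def test_smoothing_property(self, default_truth, identity_curve):
        """The SPD tracks the smoothed truth better than the raw truth."""
        from scipy.ndimage import uniform_filter1d

        spd = rc.forward_simulate_spd(
            default_truth, 5_000, (10_000, 5_881), identity_curve, seed=4
        ).restrict(10_000, 5_881)
        aligned = np.interp(
            default_truth.years.astype(float)[::-1], spd.cal_bp, spd.probability
        )[::-1]
        smoothed = uniform_filter1d(default_truth.size, 500, mode="nearest")
        corr_raw = np.corrcoef(aligned, default_truth.size)[0, 1]
        corr_smooth = np.corrcoef(aligned, smoothed)[0, 1]
        assert corr_smooth > corr_raw


@settings(max_examples=20, deadline=None)
@given(
    c14=st.floats(4_500, 11_000),
    err=st.floats(20.0, 120.0),
)
def test_calibrated_mass_always_unit(c14, err):
    curve = rc.make_identity_curve(4_000, 12_000, curve_error=8.0)
    dens = rc.calibrate(rc.RadiocarbonDate(c14, err), curve)
    assert dens.pmf.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(dens.pmf >= 0)
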