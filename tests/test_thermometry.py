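import numpy as np
import pytest
from scipy.optimize import curve_fit

from trxss import heatmodel
from trxss.datamodel import Curve1D, QGrid
from trxss.errors import InvalidArgumentError, OutOfDomainError
from trxss.reduction import (DifferenceSeries, average_repeats,
                             difference_protocol)
from trxss.synthetic import (HEAT_GAIN, KineticTruth, NoiseConfig,
                             simulate_scan, simulate_static_series,
                             water_heat_basis)
from trxss.thermometry import (calibrate, detectability, fit_temperature,
                               spatial_map)
from trxss.timing import TriggerScheme


class TestCalibrate:
    def test_noise_free_basis_equals_generator_truth(self, coarse_grid):
        curves = simulate_static_series([20.0, 25.0, 30.0, 35.0, 40.0], 20.0,
                                        NoiseConfig(seed=0, poisson=False),
                                        grid=coarse_grid)
        cal = calibrate(curves, 20.0, normalize_window=None)
        b = water_heat_basis(coarse_grid).values
        np.testing.assert_allclose(cal.basis.intensity, HEAT_GAIN * b,
                                   atol=1e-9)
        assert cal.linearity_r2 == pytest.approx(1.0)

    def test_two_point_closed_form(self, coarse_grid):
        curves = simulate_static_series([20.0, 30.0], 20.0,
                                        NoiseConfig(seed=0, poisson=False),
                                        grid=coarse_grid)
        cal = calibrate(curves, 20.0, normalize_window=None)
        slope = (curves[1].intensity - curves[0].intensity) / 10.0
        np.testing.assert_allclose(cal.basis.intensity, slope, atol=1e-12)

    def test_single_temperature_rejected(self, coarse_grid):
        curves = simulate_static_series([20.0], 20.0,
                                        NoiseConfig(seed=0), grid=coarse_grid)
        with pytest.raises(InvalidArgumentError):
            calibrate(curves, 20.0)

    def test_missing_reference_rejected(self, coarse_grid):
        curves = simulate_static_series([20.0, 30.0], 20.0,
                                        NoiseConfig(seed=0), grid=coarse_grid)
        with pytest.raises(InvalidArgumentError):
            calibrate(curves, 25.0)

    def test_noisy_series_is_almost_perfectly_linear(self, default_grid):
        curves = simulate_static_series([20.0, 25.0, 30.0, 35.0, 40.0], 20.0,
                                        NoiseConfig(seed=17), grid=default_grid)
        cal = calibrate(curves, 20.0)
        assert cal.linearity_r2 > 0.99


class TestFitTemperature:
    def _cal(self, grid):
        curves = simulate_static_series([20.0, 30.0], 20.0,
                                        NoiseConfig(seed=0, poisson=False),
                                        grid=grid, n_frames=1)
        return calibrate(curves, 20.0, normalize_window=None)

    def test_basis_itself_retrieves_one_degree(self, coarse_grid):
        cal = self._cal(coarse_grid)
        times = np.arange(5) * 2e-3
        series = DifferenceSeries(coarse_grid,
                                  np.tile(cal.basis.intensity, (5, 1)), times)
        trace = fit_temperature(series, cal)
        np.testing.assert_allclose(trace.deltaT, 1.0, rtol=1e-9)

    def test_zero_signal_retrieves_zero(self, coarse_grid):
        cal = self._cal(coarse_grid)
        series = DifferenceSeries(coarse_grid,
                                  np.zeros((5, len(coarse_grid))),
                                  np.arange(5) * 2e-3)
        trace = fit_temperature(series, cal)
        np.testing.assert_allclose(trace.deltaT, 0.0)

    def test_scale_equivariance(self, coarse_grid):
        cal = self._cal(coarse_grid)
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (5, len(coarse_grid)))
        times = np.arange(5) * 2e-3
        c1 = fit_temperature(DifferenceSeries(coarse_grid, data, times), cal).c
        c3 = fit_temperature(DifferenceSeries(coarse_grid, 3 * data, times), cal).c
        np.testing.assert_allclose(c3, 3 * c1, rtol=1e-12)

    def test_noise_free_round_trip_is_exact(self, small_scheme, coarse_grid):
        """Calibration -> retrieval returns the injected jump to ~machine precision."""
        noise = NoiseConfig(seed=0, poisson=False, drift_amplitude=0.0,
                            damage_slope=0.0)
        truth = KineticTruth(tau=(0.01,), amplitudes=(0.0,), deltaT_true=9.0)
        scan = simulate_scan(small_scheme, truth, noise, n_steps=3,
                             grid=coarse_grid)
        avg = average_repeats(difference_protocol(scan))
        curves = simulate_static_series([20.0, 30.0], 20.0, noise,
                                        grid=coarse_grid, n_frames=1)
        cal = calibrate(curves, 20.0, normalize_window=None)
        trace = fit_temperature(avg, cal)
        # the short secondary train holds the jump for 0.1 s after the pulse
        held = (trace.times >= small_scheme.dt1) & \
               (trace.times <= small_scheme.dt1 + small_scheme.train_duration)
        np.testing.assert_allclose(trace.deltaT[held], 9.0, rtol=1e-9)

    def test_no_overlap_with_fit_range_rejected(self, coarse_grid):
        cal = self._cal(coarse_grid)
        series = DifferenceSeries(coarse_grid,
                                  np.zeros((2, len(coarse_grid))),
                                  np.arange(2) * 2e-3)
        with pytest.raises(InvalidArgumentError):
            fit_temperature(series, cal, fit_range=(5.0, 6.0))

    def test_baseline_mismatch_warns(self, coarse_grid):
        cal = self._cal(coarse_grid)
        series = DifferenceSeries(coarse_grid,
                                  np.zeros((2, len(coarse_grid))),
                                  np.arange(2) * 2e-3)
        with pytest.warns(UserWarning, match="baseline"):
            fit_temperature(series, cal, baseline_temperature=35.0)

    def test_cooling_constant_recovered_for_transient_jump(self, default_grid):
        """A non-maintained jump decays with the generator's cooling constant."""
        scheme = TriggerScheme(train_duration=0.0, step_duration=2.0, dt1=0.5)
        truth = KineticTruth(tau=(0.05,), amplitudes=(0.0,), deltaT_true=13.1,
                             maintained=False, cooling_tau=0.2)
        scan = simulate_scan(scheme, truth, NoiseConfig(seed=23), n_steps=81,
                             grid=default_grid)
        avg = average_repeats(difference_protocol(scan,
                                                  normalize_window=(1.45, 1.55)))
        curves = simulate_static_series([20.0, 25.0, 30.0, 35.0], 20.0,
                                        NoiseConfig(seed=5), grid=default_grid)
        cal = calibrate(curves, 20.0)
        trace = fit_temperature(avg, cal)
        t = trace.times - scheme.dt1

        def causal_decay(tt, a, tau, c):
            return c + a * np.exp(-np.maximum(tt, 0) / tau) * (tt >= 0)

        popt, _ = curve_fit(causal_decay, t, trace.deltaT, p0=(13.0, 0.3, 0.0))
        assert popt[1] == pytest.approx(0.2, rel=0.10)


class TestDetectability:
    def _repeats(self, n, seed=31):
        scheme = TriggerScheme(train_duration=3.0)
        truth = KineticTruth(tau=(1.0,), amplitudes=(0.0,), deltaT_true=5.0)
        grid = None
        scan = simulate_scan(scheme, truth, NoiseConfig(seed=seed),
                             n_steps=2 * n + 1)
        return difference_protocol(scan, normalize_window=(1.45, 1.55))

    def test_spread_shrinks_with_averaging(self, default_grid):
        series = self._repeats(20)
        curves = simulate_static_series([20.0, 30.0, 40.0], 20.0,
                                        NoiseConfig(seed=6), grid=default_grid)
        cal = calibrate(curves, 20.0)
        window = (1.5, 3.5)
        spreads = [detectability(series, cal, n, window, truth=5.0,
                                 n_draws=60, seed=1)["std"]
                   for n in (2, 5, 10)]
        assert spreads[0] > spreads[1] > spreads[2]

    def test_five_step_average_detects_a_five_degree_jump(self, default_grid):
        series = self._repeats(20, seed=37)
        curves = simulate_static_series([20.0, 30.0, 40.0], 20.0,
                                        NoiseConfig(seed=6), grid=default_grid)
        cal = calibrate(curves, 20.0)
        out = detectability(series, cal, 5, (1.5, 3.5), truth=5.0,
                            tolerance=2.0, n_draws=60, seed=2)
        assert out["fraction_within"] > 0.9
        assert out["mean"] == pytest.approx(5.0, abs=1.0)

    def test_insufficient_repeats_rejected(self, default_grid):
        series = self._repeats(3)
        curves = simulate_static_series([20.0, 30.0], 20.0,
                                        NoiseConfig(seed=6), grid=default_grid)
        cal = calibrate(curves, 20.0)
        with pytest.raises(InvalidArgumentError):
            detectability(series, cal, 10, (1.5, 3.5))


class TestSpatialMap:
    def test_constant_field(self):
        pts = [(y, z, 7.5) for y in (0.0, 1e-4, 2e-4) for z in (0.0, 1e-4)]
        m = spatial_map(pts, spacing=1e-4)
        assert m(1.3e-4, 0.6e-4) == pytest.approx(7.5)

    def test_linear_field_is_exact(self):
        pts = [(y, z, 2.0 * y + 3.0 * z) for y in np.arange(5) * 1e-4
               for z in np.arange(4) * 1e-4]
        m = spatial_map(pts)
        y, z = 1.7e-4, 2.3e-4
        assert m(y, z) == pytest.approx(2.0 * y + 3.0 * z, rel=1e-9)
        assert m.beam_average((2e-4, 1.5e-4), (1e-4, 1e-4)) == \
            pytest.approx(2.0 * 2e-4 + 3.0 * 1.5e-4, rel=1e-9)

    def test_query_outside_hull_rejected(self):
        pts = [(y, z, 1.0) for y in (0.0, 1e-4) for z in (0.0, 1e-4)]
        m = spatial_map(pts)
        with pytest.raises(OutOfDomainError):
            m(5e-4, 0.0)

    def test_incomplete_or_collinear_grids_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spatial_map([(0, 0, 1), (1, 0, 2), (2, 0, 3)])   # collinear
        with pytest.raises(InvalidArgumentError):
            spatial_map([(0, 0, 1), (1, 0, 2), (0, 1, 3)])   # incomplete
        with pytest.raises(InvalidArgumentError):
            spatial_map([(0, 0, 1), (1, 1, 2)])

    def test_heat_model_field_on_survey_grid(self):
        """100 µm sampling reproduces the dense field away from the entry wall."""
        config = heatmodel.HeatConfig()
        field = heatmodel.deposit(config)
        spacing = 100e-6
        ys = np.arange(-0.7e-3, 0.7e-3 + 1e-9, spacing)
        zs = np.arange(0.05e-3, 1.45e-3 + 1e-9, spacing)
        pts = [(y, z, float(np.interp(y, field.x, np.ones_like(field.x)) *
                            0.0)) for y in ys for z in zs]
        # sample the true field bilinearly at the survey nodes
        from trxss.heatmodel import beam_average
        def dense(y, z):
            i = np.interp(y, field.x, np.arange(field.x.size))
            j = np.interp(z, field.z, np.arange(field.z.size))
            i0, j0 = int(min(i, field.x.size - 2)), int(min(j, field.z.size - 2))
            fy, fz = i - i0, j - j0
            d = field.dT
            return ((1 - fy) * (1 - fz) * d[i0, j0] + fy * (1 - fz) * d[i0 + 1, j0]
                    + (1 - fy) * fz * d[i0, j0 + 1] + fy * fz * d[i0 + 1, j0 + 1])
        pts = [(y, z, dense(y, z)) for y in ys for z in zs]
        m = spatial_map(pts, spacing=spacing)
        peak = field.dT.max()
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(300):
            y = rng.uniform(-0.6e-3, 0.6e-3)
            z = rng.uniform(0.2e-3, 1.4e-3)   # away from the steep entry gradient
            errs.append(abs(m(y, z) - dense(y, z)))
        assert max(errs) < 0.05 * peak
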