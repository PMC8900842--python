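import numpy as np
import pytest

from trxss.datamodel import QGrid, Scan, Step
from trxss.errors import (DegenerateInputError, InvalidArgumentError,
                          ValidationError)
from trxss.reduction import (DifferenceSeries, average_repeats,
                             difference_protocol, normalize_curve,
                             normalize_scan, off_off_control,
                             subtract_solvent_heating)
from trxss.synthetic import (KineticTruth, NoiseConfig, protein_diff_basis,
                             simulate_scan, simulate_solvent_scan,
                             water_heat_basis)
from trxss.timing import TriggerScheme

WIN = (1.45, 1.55)


def _scan_from_matrices(matrices, scheme, grid):
    steps = []
    for i, m in enumerate(matrices):
        steps.append(Step(index=i, laser_state="off" if i % 2 == 0 else "on",
                          frames=np.asarray(m, dtype=float),
                          frame_times=np.arange(np.asarray(m).shape[0])
                          * scheme.frame_period,
                          exposure=scheme.frame_live_time(), t0=i * 0.2))
    return Scan(grid, steps, scheme)


@pytest.fixture(scope="module")
def tiny():
    grid = QGrid(np.array([0.1, 0.2, 1.45, 1.5, 1.55, 2.0, 2.1]))
    scheme = TriggerScheme(step_duration=3 * 2e-3, dt1=0.0, tw1=0.0,
                           train_duration=0.0)
    return grid, scheme


class TestNormalize:
    def test_identical_frame_has_unit_scale(self, tiny):
        grid, scheme = tiny
        base = np.full((3, 7), 50.0)
        scan = _scan_from_matrices([base, base, base], scheme, grid)
        _, scales = normalize_scan(scan, WIN)
        np.testing.assert_allclose(scales, 1.0)

    def test_ten_percent_drift_is_removed(self, tiny):
        grid, scheme = tiny
        base = np.full((3, 7), 50.0)
        scan = _scan_from_matrices([base, 1.1 * base, base], scheme, grid)
        _, scales = normalize_scan(scan, WIN)
        np.testing.assert_allclose(scales[1], 1 / 1.1)

    def test_curve_scale_factor(self, tiny):
        grid, _ = tiny
        from trxss.datamodel import Curve1D
        ref = Curve1D(grid, np.full(7, 50.0))
        curve = Curve1D(grid, np.full(7, 55.0))
        scaled, s = normalize_curve(curve, ref, WIN)
        assert s == pytest.approx(1 / 1.1)
        np.testing.assert_allclose(scaled.intensity, 50.0)

    def test_sawtooth_drift_flattened(self, small_scheme, coarse_grid):
        """Post-normalisation frame-to-frame window variation < 0.1% (noise-free)."""
        truth = KineticTruth(tau=(1.0,), amplitudes=(0.0,), deltaT_true=0.0)
        noise = NoiseConfig(seed=9, poisson=False, injection_period=2.0)
        scan = simulate_scan(small_scheme, truth, noise, n_steps=5,
                             grid=coarse_grid)
        normed, _ = normalize_scan(scan, WIN, mode="frame")
        mask = coarse_grid.window(*WIN)
        integrals = np.concatenate(
            [np.trapezoid(s.frames[:, mask], coarse_grid.q[mask], axis=1)
             for s in normed.steps])
        assert integrals.std() / integrals.mean() < 1e-3

    def test_degenerate_window_integral(self, tiny):
        grid, scheme = tiny
        scan = _scan_from_matrices([np.zeros((3, 7))] * 3, scheme, grid)
        with pytest.raises(DegenerateInputError):
            normalize_scan(scan, WIN)


class TestDifferenceProtocol:
    def test_identical_flanking_steps_give_zero(self, tiny):
        grid, scheme = tiny
        a = np.random.default_rng(0).uniform(10, 20, (3, 7))
        scan = _scan_from_matrices([a, a, a], scheme, grid)
        (series,) = difference_protocol(scan)
        np.testing.assert_allclose(series.delta_I, 0.0, atol=1e-12)

    def test_linear_ramp_cancels_exactly(self, tiny):
        grid, scheme = tiny
        a = np.random.default_rng(1).uniform(10, 20, (3, 7))
        eps = np.random.default_rng(2).uniform(0, 1, (3, 7))
        signal = np.random.default_rng(3).uniform(0, 5, (3, 7))
        scan = _scan_from_matrices([a, a + eps + signal, a + 2 * eps],
                                   scheme, grid)
        (series,) = difference_protocol(scan)
        np.testing.assert_allclose(series.delta_I, signal, atol=1e-12)

    def test_is_linear_in_the_signal(self, small_scheme, coarse_grid):
        nf = dict(poisson=False, drift_amplitude=0.0, damage_slope=0.0)
        tA = KineticTruth(tau=(0.05,), amplitudes=(1.0,), deltaT_true=0.0)
        tB = KineticTruth(tau=(1.0,), amplitudes=(0.0,), deltaT_true=8.0)
        tAB = KineticTruth(tau=(0.05,), amplitudes=(1.0,), deltaT_true=8.0)
        out = {}
        for key, truth in (("A", tA), ("B", tB), ("AB", tAB)):
            scan = simulate_scan(small_scheme, truth, NoiseConfig(seed=0, **nf),
                                 n_steps=3, grid=coarse_grid)
            out[key] = difference_protocol(scan)[0].delta_I
        np.testing.assert_allclose(out["AB"], out["A"] + out["B"], atol=1e-9)

    def test_gain_invariance_after_normalization(self, small_scheme, coarse_grid):
        truth = KineticTruth(tau=(0.05,), amplitudes=(1.0,), deltaT_true=8.0)
        noise = NoiseConfig(seed=5, poisson=False)
        scan = simulate_scan(small_scheme, truth, noise, n_steps=3,
                             grid=coarse_grid)
        scaled = Scan(scan.grid,
                      [Step(s.index, s.laser_state, 3.0 * s.frames,
                            s.frame_times, s.exposure, s.t0)
                       for s in scan.steps],
                      scan.scheme, metadata=dict(scan.metadata))
        na, _ = normalize_scan(scan, WIN, reference=1.0)
        nb, _ = normalize_scan(scaled, WIN, reference=1.0)
        a = difference_protocol(na)[0].delta_I
        b = difference_protocol(nb)[0].delta_I
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_scan_without_on_steps_rejected(self, tiny):
        grid, scheme = tiny
        scan = _scan_from_matrices([np.full((3, 7), 5.0)], scheme, grid)
        with pytest.raises(ValidationError):
            difference_protocol(scan)


class TestOffOffControl:
    def test_requires_three_off_steps(self, tiny):
        grid, scheme = tiny
        scan = _scan_from_matrices([np.full((3, 7), 5.0)] * 3, scheme, grid)
        with pytest.raises(InvalidArgumentError):
            off_off_control(scan)

    def test_noise_free_control_is_zero(self, small_scheme, coarse_grid):
        truth = KineticTruth(deltaT_true=10.0)
        scan = simulate_scan(small_scheme, truth, NoiseConfig(seed=3, poisson=False),
                             n_steps=5, grid=coarse_grid)
        control = off_off_control(scan, normalize_window=WIN)
        assert np.abs(control.delta_I).max() < 1e-7 * 5000

    def test_noisy_control_mean_is_consistent_with_zero(self, small_scheme,
                                                        coarse_grid):
        scan = simulate_scan(small_scheme, KineticTruth(), NoiseConfig(seed=8),
                             n_steps=9, grid=coarse_grid)
        control = off_off_control(scan, normalize_window=WIN)
        grand_mean = control.delta_I.mean()
        # null distribution: mean of n_frames*n_q*n_ctrl variates of var 2*I
        n = control.delta_I.size * 2
        sem = np.sqrt(2 * 5000 / n)
        assert abs(grand_mean) < 4 * sem


class TestAverageRepeats:
    def test_single_series_has_no_sem(self, tiny):
        grid, _ = tiny
        ds = DifferenceSeries(grid, np.ones((3, 7)), np.arange(3) * 2e-3)
        out = average_repeats([ds])
        assert out.sem is None
        np.testing.assert_array_equal(out.delta_I, ds.delta_I)

    def test_identical_series_have_zero_sem(self, tiny):
        grid, _ = tiny
        ds = [DifferenceSeries(grid, np.ones((3, 7)), np.arange(3) * 2e-3)
              for _ in range(4)]
        out = average_repeats(ds)
        assert out.n_repeats == 4
        np.testing.assert_allclose(out.sem, 0.0)

    def test_mismatched_shapes_rejected(self, tiny):
        grid, _ = tiny
        a = DifferenceSeries(grid, np.ones((3, 7)), np.arange(3) * 2e-3)
        b = DifferenceSeries(grid, np.ones((4, 7)), np.arange(4) * 2e-3)
        with pytest.raises(ValidationError):
            average_repeats([a, b])
        with pytest.raises(InvalidArgumentError):
            average_repeats([])

    def test_sem_shrinks_as_inverse_sqrt_n(self, tiny):
        """Resampling check of the 1/sqrt(N) law on iid noise."""
        grid, _ = tiny
        rng = np.random.default_rng(12)
        pool = [DifferenceSeries(grid, rng.normal(0, 1, (20, 7)),
                                 np.arange(20) * 2e-3) for _ in range(64)]
        ns = [4, 8, 16, 32, 64]
        sems = [average_repeats(pool[:n]).sem.mean() for n in ns]
        slope = np.polyfit(np.log(ns), np.log(sems), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


class TestSolventSubtraction:
    def _series(self, grid, matrix, times):
        return DifferenceSeries(grid, matrix, times)

    def test_sample_equal_solvent_gives_zero_and_unit_scale(self, coarse_grid):
        b = water_heat_basis(coarse_grid).values
        times = np.arange(10) * 2e-3
        heat = np.outer(np.linspace(1, 2, 10), 100 * b)
        sample = self._series(coarse_grid, heat.copy(), times)
        solvent = self._series(coarse_grid, heat.copy(), times)
        out, s = subtract_solvent_heating(sample, solvent)
        np.testing.assert_allclose(s, 1.0, rtol=1e-9)
        np.testing.assert_allclose(out.delta_I, 0.0, atol=1e-9)

    def test_scaled_solvent_plus_protein_recovers_protein(self, coarse_grid):
        b = water_heat_basis(coarse_grid).values
        p = protein_diff_basis(coarse_grid).values
        times = np.arange(10) * 2e-3
        solvent = np.outer(np.ones(10), 100 * b)
        protein = np.outer(np.linspace(0, 1, 10), 50 * p)
        sample = self._series(coarse_grid, 2 * solvent + protein, times)
        out, s = subtract_solvent_heating(
            self._series(coarse_grid, sample.delta_I, times),
            self._series(coarse_grid, solvent, times))
        np.testing.assert_allclose(s, 2.0, rtol=1e-9)
        np.testing.assert_allclose(out.delta_I, protein, atol=1e-8)

    def test_pure_protein_signal_is_untouched(self, coarse_grid):
        b = water_heat_basis(coarse_grid).values
        p = protein_diff_basis(coarse_grid).values
        times = np.arange(10) * 2e-3
        protein = np.outer(np.linspace(0, 1, 10), 50 * p)
        solvent = np.outer(np.ones(10), 100 * b)
        out, s = subtract_solvent_heating(
            self._series(coarse_grid, protein, times),
            self._series(coarse_grid, solvent, times))
        assert np.abs(s).max() < 1e-6
        np.testing.assert_allclose(out.delta_I, protein, atol=1e-4)

    def test_vanishing_solvent_in_window_rejected(self, coarse_grid):
        times = np.arange(5) * 2e-3
        sample = self._series(coarse_grid, np.ones((5, len(coarse_grid))), times)
        solvent = self._series(coarse_grid, np.zeros((5, len(coarse_grid))), times)
        with pytest.raises(DegenerateInputError):
            subtract_solvent_heating(sample, solvent)


class TestEndToEndRecovery:
    def test_injected_signal_recovered_within_three_sem(self, standard_scheme):
        """Averaged differences match the injected ΔT·b + α·p frame by frame."""
        from trxss.synthetic import default_grid as dg, HEAT_GAIN, PROTEIN_AMPLITUDE
        grid = dg(saxs_step=0.02, waxs_step=0.02)
        truth = KineticTruth()
        noise = NoiseConfig(seed=21, drift_amplitude=0.0, damage_slope=0.0)
        scan = simulate_scan(standard_scheme, truth, noise, n_steps=21, grid=grid)
        # clean generator config: differencing alone isolates the signal, so the
        # comparison is free of the (separately tested) normalisation distortion
        series = difference_protocol(scan)
        avg = average_repeats(series)
        t_rel = avg.times - standard_scheme.dt1
        b = water_heat_basis(grid).values
        p = protein_diff_basis(grid).values
        expected = (np.outer(truth.deltaT_profile(t_rel, 3.0) * HEAT_GAIN, b)
                    + np.outer(truth.occupancy(t_rel) * PROTEIN_AMPLITUDE, p))
        # adjacent on-series share a flanking off step (cov = sigma^2/4 of the
        # sigma^2*3/2 per-series variance), so the naive SEM underestimates the
        # standard error of the mean by sqrt(2/1.25); compare at 3 true SEs
        z = (avg.delta_I - expected) / (avg.sem * np.sqrt(2.0 / 1.25))
        assert np.mean(np.abs(z) < 3) > 0.985
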