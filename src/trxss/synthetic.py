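"""Seeded generator of synthetic T-jump scattering data.

Emulates the statistical structure the analysis chain assumes, so the whole
pipeline is testable without beamline data:

* a water difference-heating WAXS signature, linear in ΔT, with isosbestic
  zeros pinned at q = 1.5 and 2.1 1/Å;
* a low-q protein difference signal (expansion signature, negative at the
  lowest q) whose occupancy rises exponentially after the laser pulse;
* Poisson photon noise at ~1e12 photons/s and ~2 ms frames;
* a ~10% sawtooth incident-intensity drift with a 10 min injection period,
  phase-randomised per scan;
* a radiation-damage ramp that grows with the time a sample has sat in the
  beam — identical for every step because fresh sample is flushed in between,
  which is exactly why frame-matched differencing cancels it.

Absolute count levels are synthetic (documented in docs/methods.md); the
default signal amplitudes are fixed so a single 2 ms difference frame at
ΔT ≈ 15 °C sits near the detection limit and the protein signal is a ~1.5%
relative change at its low-q extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Curve1D, QGrid, Scan, Step
from .errors import InvalidArgumentError
from .timing import TriggerScheme

__all__ = [
    "WaterHeatBasis",
    "ProteinDiffBasis",
    "KineticTruth",
    "NoiseConfig",
    "default_grid",
    "water_heat_basis",
    "protein_diff_basis",
    "base_intensity",
    "simulate_scan",
    "simulate_static_series",
    "simulate_solvent_scan",
]

ISOSBESTIC_Q = (1.5, 2.1)

# signal-model constants (counts per 1.9 ms frame at 1e12 photons/s)
HEAT_GAIN = 12.0        # counts/°C along the unit-norm water heating basis
PROTEIN_AMPLITUDE = 200.0  # counts along the unit-norm protein basis at occupancy 1
BASE_FLAT = 2000.0      # flat water/background level per bin
BASE_PEAK = 3000.0      # broad water structure peak near q ~ 2 1/Å
BASE_PROTEIN = 1500.0   # static protein (Guinier-like) forward scattering
REF_FLUX = 1e12         # photons/s at which the count levels above are defined
REF_LIVE_TIME = 1.9e-3  # s


def default_grid(saxs_step: float = 0.01, waxs_step: float = 0.01) -> QGrid:
    """Default SAXS+WAXS grid: 0.03-0.59 and 1.45-2.50 1/Å, disjoint windows."""
    saxs = np.round(np.arange(0.03, 0.60 - 1e-12, saxs_step), 10)
    waxs = np.round(np.arange(1.45, 2.50 + 1e-12, waxs_step), 10)
    return QGrid(np.concatenate([saxs, waxs]))


# ---------------------------------------------------------------------------
# spectral bases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterHeatBasis:
    """Unit-norm per-degree water heating shape b(q); zero at the isosbestics."""

    grid: QGrid
    values: np.ndarray
    isosbestic_q: tuple[float, float] = ISOSBESTIC_Q

    def __call__(self, q) -> np.ndarray:
        return np.interp(q, self.grid.q, self.values)


@dataclass(frozen=True)
class ProteinDiffBasis:
    """Unit-norm protein difference shape p(q); negative at the lowest q."""

    grid: QGrid
    values: np.ndarray
    rg_before: float = 14.0
    rg_after: float = 15.0


def _heat_shape(q: np.ndarray, iso=ISOSBESTIC_Q, center: float = 1.8,
                width: float = 0.3) -> np.ndarray:
    # -(q-q1)(q-q2) * Gaussian envelope: zeros exactly at the isosbestic points,
    # sign pattern (-, +, -) around them, negligible outside the WAXS window.
    return -(q - iso[0]) * (q - iso[1]) * np.exp(-((q - center) ** 2) / (2 * width**2))


def water_heat_basis(grid: QGrid, isosbestic_q=ISOSBESTIC_Q) -> WaterHeatBasis:
    """Construct the per-degree water heating basis on ``grid`` (‖b‖₂ = 1).

    The grid must bracket both isosbestic points so the zero crossings are
    representable on it.
    """
    q1, q2 = isosbestic_q
    if grid.q[0] > q1 or grid.q[-1] < q2:
        raise InvalidArgumentError(
            f"grid [{grid.q[0]}, {grid.q[-1]}] does not cover the isosbestic "
            f"points {isosbestic_q}"
        )
    b = _heat_shape(grid.q, isosbestic_q)
    norm = np.linalg.norm(b)
    return WaterHeatBasis(grid, b / norm, tuple(isosbestic_q))


def protein_diff_basis(grid: QGrid, rg_before: float = 14.0,
                       rg_after: float = 15.0) -> ProteinDiffBasis:
    """Expansion difference signal: Guinier(Rg_after) - Guinier(Rg_before), ‖p‖₂=1."""
    if rg_after <= rg_before:
        raise InvalidArgumentError("rg_after must exceed rg_before for an expansion")
    q = grid.q
    p = np.exp(-(q**2) * rg_after**2 / 3.0) - np.exp(-(q**2) * rg_before**2 / 3.0)
    return ProteinDiffBasis(grid, p / np.linalg.norm(p), rg_before, rg_after)


def base_intensity(grid: QGrid, include_protein: bool = True) -> np.ndarray:
    """Static expected counts per frame: water background (+ protein Guinier)."""
    q = grid.q
    base = BASE_FLAT + BASE_PEAK * np.exp(-((q - 2.0) ** 2) / (2 * 0.25**2))
    if include_protein:
        base = base + BASE_PROTEIN * np.exp(-(q**2) * 14.0**2 / 3.0)
    return base


# ---------------------------------------------------------------------------
# ground truth and noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTruth:
    """Injected ground truth for one scan.

    ``tau``/``amplitudes`` define the occupancy α(t) = Σ aᵢ (1 - exp(-t/τᵢ))
    of the high-temperature protein state (t measured from the laser pulse);
    ``deltaT_true`` is the plateau temperature jump.  A *maintained* jump
    holds ΔT for the secondary-train duration and decays afterwards; a
    non-maintained jump decays immediately with ``cooling_tau``.

    Defaults are the 20 °C baseline condition: ΔT = 13.1 °C, τ = 4.46 s.
    """

    tau: tuple[float, ...] = (4.46,)
    amplitudes: tuple[float, ...] = (1.0,)
    deltaT_true: float = 13.1
    maintained: bool = True
    cooling_tau: float = 0.2

    def __post_init__(self):
        if len(self.tau) != len(self.amplitudes):
            raise InvalidArgumentError("tau and amplitudes must have equal length")
        if any(t <= 0 for t in self.tau):
            raise InvalidArgumentError("all tau must be > 0")
        if any(a < 0 for a in self.amplitudes) or sum(self.amplitudes) > 1 + 1e-12:
            raise InvalidArgumentError("amplitudes must be >= 0 and sum to <= 1")
        if self.cooling_tau <= 0:
            raise InvalidArgumentError("cooling_tau must be > 0")

    def occupancy(self, t) -> np.ndarray:
        """α(t) in [0, 1]; zero before the pulse (t < 0)."""
        t = np.asarray(t, dtype=float)
        alpha = np.zeros_like(t)
        pos = t >= 0
        for tau, amp in zip(self.tau, self.amplitudes):
            alpha[pos] += amp * (1.0 - np.exp(-t[pos] / tau))
        return alpha

    def deltaT_profile(self, t, hold_duration: float) -> np.ndarray:
        """ΔT(t) in °C; t from the pulse.  Held for ``hold_duration`` if maintained."""
        t = np.asarray(t, dtype=float)
        dT = np.zeros_like(t)
        pos = t >= 0
        if self.maintained and hold_duration > 0:
            held = pos & (t <= hold_duration)
            after = pos & (t > hold_duration)
            dT[held] = self.deltaT_true
            dT[after] = self.deltaT_true * np.exp(-(t[after] - hold_duration) / self.cooling_tau)
        else:
            dT[pos] = self.deltaT_true * np.exp(-t[pos] / self.cooling_tau)
        return dT


@dataclass(frozen=True)
class NoiseConfig:
    """Photon statistics and slow systematic effects of the beamline."""

    flux: float = 1e12              # photons/s
    drift_amplitude: float = 0.10   # fractional sawtooth depth between injections
    injection_period: float = 600.0  # s
    damage_slope: float = 0.01      # fractional intensity change per s in beam
    seed: int = 0
    poisson: bool = True            # False -> return expected counts (noise-free)

    def __post_init__(self):
        if self.flux <= 0:
            raise InvalidArgumentError("flux must be > 0")
        if not 0 <= self.drift_amplitude < 1:
            raise InvalidArgumentError("drift_amplitude must lie in [0, 1)")
        if self.injection_period <= 0:
            raise InvalidArgumentError("injection_period must be > 0")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _gain(t_abs: np.ndarray, noise: NoiseConfig, phase: float) -> np.ndarray:
    """Sawtooth incident-intensity factor: 1.0 falling to 1-drift each period."""
    frac = np.mod(t_abs + phase, noise.injection_period) / noise.injection_period
    return 1.0 - noise.drift_amplitude * frac


def simulate_scan(
    scheme: TriggerScheme,
    truth: KineticTruth,
    noise: NoiseConfig,
    n_steps: int = 21,
    grid: QGrid | None = None,
    include_protein: bool = True,
    heat_gain: float = HEAT_GAIN,
    protein_amplitude: float = PROTEIN_AMPLITUDE,
    step_gap: float = 0.0,
    baseline_temperature: float = 20.0,
) -> Scan:
    """Simulate one alternating off/on scan.

    Expected counts for frame at in-step time t (absolute time T)::

        gain(T) * damage(t) * scale * [ I_base(q)
            + on * ( ΔT(t - dt1) * heat_gain * b(q)
                     + α(t - dt1) * protein_amplitude * p(q) ) ]

    with ``scale = (flux / 1e12) * (live_time / 1.9 ms)`` and Poisson sampling
    unless ``noise.poisson`` is False.  ``n_steps`` must be odd so the scan
    begins and ends laser-off.  Identical seed -> identical scan.
    """
    if n_steps < 1 or n_steps % 2 == 0:
        raise InvalidArgumentError(f"n_steps must be odd (got {n_steps}) so the "
                                   "scan begins and ends with a laser-off step")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(noise.seed)
    phase = float(rng.uniform(0.0, noise.injection_period))

    b = water_heat_basis(grid).values
    p = protein_diff_basis(grid).values if include_protein else np.zeros(len(grid))
    base = base_intensity(grid, include_protein=include_protein)
    live = scheme.frame_live_time()
    scale = (noise.flux / REF_FLUX) * (live / REF_LIVE_TIME)
    times = scheme.frame_times()
    hold = scheme.train_duration if scheme.train_duration > 0 else 0.0

    steps = []
    for i in range(n_steps):
        t0 = i * (scheme.step_duration + step_gap)
        on = i % 2 == 1
        expected = np.outer(
            _gain(t0 + times, noise, phase) * (1.0 + noise.damage_slope * times),
            base,
        )
        if on:
            t_rel = times - scheme.dt1
            dT = truth.deltaT_profile(t_rel, hold)
            alpha = truth.occupancy(t_rel)
            signal = np.outer(dT * heat_gain, b) + np.outer(alpha * protein_amplitude, p)
            gain_damage = _gain(t0 + times, noise, phase) * (1.0 + noise.damage_slope * times)
            expected = expected + signal * gain_damage[:, None]
        expected *= scale
        frames = rng.poisson(expected).astype(float) if noise.poisson else expected
        steps.append(
            Step(index=i, laser_state="on" if on else "off", frames=frames,
                 frame_times=times.copy(), exposure=live, t0=t0)
        )
    metadata = {
        "seed": noise.seed,
        "drift_phase": phase,
        "baseline_temperature": baseline_temperature,
        "deltaT_true": truth.deltaT_true,
        "tau_true": list(truth.tau),
        "amplitudes_true": list(truth.amplitudes),
        "maintained": truth.maintained,
        "include_protein": include_protein,
        "heat_gain": heat_gain,
        "protein_amplitude": protein_amplitude,
    }
    return Scan(grid, steps, scheme, metadata=metadata)


def simulate_solvent_scan(
    scheme: TriggerScheme,
    deltaT: float,
    noise: NoiseConfig,
    n_steps: int = 21,
    grid: QGrid | None = None,
    maintained: bool = True,
    cooling_tau: float = 0.2,
    heat_gain: float = HEAT_GAIN,
) -> Scan:
    """Pure-solvent T-jump scan: same heating signal, no protein contribution."""
    truth = KineticTruth(tau=(1.0,), amplitudes=(0.0,), deltaT_true=deltaT,
                         maintained=maintained, cooling_tau=cooling_tau)
    return simulate_scan(scheme, truth, noise, n_steps=n_steps, grid=grid,
                         include_protein=False, heat_gain=heat_gain,
                         protein_amplitude=0.0)


def simulate_static_series(
    temperatures,
    reference: float,
    noise: NoiseConfig,
    grid: QGrid | None = None,
    n_frames: int = 1000,
    heat_gain: float = HEAT_GAIN,
    include_protein: bool = False,
) -> list[Curve1D]:
    """Static calibration series: one averaged curve per bath temperature.

    Each curve is the mean of ``n_frames`` Poisson frames of
    ``gain_T * [I_base + (T - reference) * heat_gain * b(q)]`` where ``gain_T``
    is a per-temperature incident-intensity factor drawn from the drift range
    (curves at different temperatures are measured at different times).  With
    ``noise.poisson`` False the curves are exact and ``gain_T = 1``.
    """
    temperatures = list(temperatures)
    if not temperatures:
        raise InvalidArgumentError("temperature list is empty")
    if not any(abs(t - reference) < 1e-9 for t in temperatures):
        raise InvalidArgumentError(
            f"reference temperature {reference} must be in the measured series"
        )
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(noise.seed)
    b = water_heat_basis(grid).values
    base = base_intensity(grid, include_protein=include_protein)
    curves = []
    for T in temperatures:
        expected = base + (T - reference) * heat_gain * b
        if noise.poisson:
            gain = 1.0 - noise.drift_amplitude * rng.uniform()
            counts = rng.poisson(np.maximum(expected, 0.0) * gain * n_frames) / n_frames
            sigma = np.sqrt(np.maximum(expected * gain, 0.0) / n_frames)
        else:
            counts = expected.copy()
            sigma = np.zeros_like(expected)
        curves.append(
            Curve1D(grid, counts, sigma, temperature_label=float(T),
                    metadata={"reference_temperature": str(reference)})
        )
    return curves
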