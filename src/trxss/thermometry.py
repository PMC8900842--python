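"""WAXS thermometry: calibrate and retrieve the temperature jump.

Water's wide-angle scattering changes shape reproducibly with temperature,
with isosbestic points at q ≈ 1.5 and 2.1 1/Å; the amplitude of the
difference signal is, over tens of degrees, linear in ΔT.  A static series
of curves at known bath temperatures therefore calibrates a per-degree basis
ΔI_heat(q), and the jump in a time-resolved difference series is retrieved
frame by frame as the least-squares scalar c(t) in
ΔI(q, t) = c(t) · ΔI_heat(q), so ΔT(t) = c(t) in °C.

Calibration and retrieval must share the normalisation convention (both are
normalised to the water scattering around the isosbestic point) and ideally
the same baseline temperature; a differing baseline triggers a warning, not
an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .datamodel import Curve1D, QGrid
from .errors import DegenerateInputError, InvalidArgumentError, OutOfDomainError
from .reduction import DifferenceSeries, NORMALIZE_WINDOW, average_repeats, normalize_curve

__all__ = [
    "CalibrationModel",
    "TemperatureTrace",
    "WAXS_FIT_RANGE",
    "calibrate",
    "fit_temperature",
    "detectability",
    "spatial_map",
    "SpatialMap",
]

WAXS_FIT_RANGE = (1.45, 2.5)


@dataclass
class CalibrationModel:
    """Per-degree water heating basis with its provenance."""

    basis: Curve1D                  # ΔI_heat(q) per °C, on the calibration grid
    reference_temperature: float    # °C
    fit_range: tuple[float, float] = WAXS_FIT_RANGE
    linearity_r2: float = 1.0       # amplitude-vs-ΔT goodness of fit
    reference_level: float | None = None  # isosbestic-window integral the basis
    # is normalised to; lets retrieval match a scan's own reference level

    def __post_init__(self):
        mask = self.basis.grid.window(*self.fit_range)
        if np.linalg.norm(self.basis.intensity[mask]) <= 0:
            raise DegenerateInputError("calibration basis is zero on the fit range")
        if not 0.0 <= self.linearity_r2 <= 1.0:
            raise InvalidArgumentError("linearity_r2 must lie in [0, 1]")

    def basis_on(self, grid: QGrid) -> np.ndarray:
        """Basis resampled onto a data grid by linear interpolation.

        This is the only interpolation in the reduction/thermometry chain;
        everywhere else grids must match exactly.
        """
        if grid.same_as(self.basis.grid):
            return self.basis.intensity.copy()
        return np.interp(grid.q, self.basis.grid.q, self.basis.intensity)


@dataclass
class TemperatureTrace:
    """Per-frame retrieved jump: scale c(t) and ΔT(t) = c(t) °C."""

    times: np.ndarray
    c: np.ndarray
    deltaT: np.ndarray
    sem: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.deltaT = np.asarray(self.deltaT, dtype=float)
        if not (self.times.shape == self.c.shape == self.deltaT.shape):
            raise InvalidArgumentError("times, c and deltaT must have equal length")

    def plateau_mean(self, t_lo: float, t_hi: float) -> float:
        """Mean retrieved ΔT over frames with t in [t_lo, t_hi]."""
        mask = (self.times >= t_lo) & (self.times <= t_hi)
        if not mask.any():
            raise InvalidArgumentError(f"no frames in [{t_lo}, {t_hi}] s")
        return float(self.deltaT[mask].mean())


def calibrate(
    static_series,
    reference_temperature: float,
    fit_range=WAXS_FIT_RANGE,
    normalize_window=NORMALIZE_WINDOW,
) -> CalibrationModel:
    """Build a per-degree heating basis from a static temperature series.

    Curves are normalised to the reference curve's isosbestic-window
    integral, differenced against the reference, and regressed bin-wise
    (through the origin) on ΔT; the slope curve is the basis.  The linearity
    diagnostic regresses each difference's amplitude along the basis onto its
    ΔT and reports r².

    Both the calibration and the time-resolved reduction express intensities
    relative to their own reference frame's isosbestic-window integral; the
    basis therefore records that level so :func:`fit_temperature` can rescale
    it onto a scan normalised to a different level (incident-flux drifts make
    the two references differ by up to the drift amplitude).
    """
    curves = list(static_series)
    if len(curves) < 2:
        raise InvalidArgumentError("calibration needs at least two temperatures")
    grid = curves[0].grid
    for c in curves[1:]:
        if not c.grid.same_as(grid):
            raise InvalidArgumentError("all calibration curves must share one grid")
    labels = [c.temperature_label for c in curves]
    if any(label is None for label in labels):
        raise InvalidArgumentError("every calibration curve needs a temperature_label")
    ref_idx = int(np.argmin([abs(t - reference_temperature) for t in labels]))
    if abs(labels[ref_idx] - reference_temperature) > 1e-6:
        raise InvalidArgumentError(
            f"no curve at the reference temperature {reference_temperature} °C"
        )
    ref_curve = curves[ref_idx]
    if normalize_window is not None:
        ref_norm, _ = normalize_curve(ref_curve, ref_curve, normalize_window)
        normed = [normalize_curve(c, ref_norm, normalize_window)[0] for c in curves]
    else:
        ref_norm, normed = ref_curve, curves

    dT = np.array([labels[i] - reference_temperature
                   for i in range(len(curves)) if i != ref_idx])
    diffs = np.stack([normed[i].intensity - ref_norm.intensity
                      for i in range(len(curves)) if i != ref_idx])
    denom = float(np.sum(dT**2))
    if denom <= 0:
        raise InvalidArgumentError("all calibration temperatures equal the reference")
    basis_values = (dT @ diffs) / denom

    mask = grid.window(*fit_range)
    bb = float(basis_values[mask] @ basis_values[mask])
    if bb <= 0:
        raise DegenerateInputError("calibration basis vanishes on the fit range")
    amplitudes = diffs[:, mask] @ basis_values[mask] / bb
    # r² of amplitude = ΔT through the origin
    ss_res = float(np.sum((amplitudes - dT) ** 2))
    ss_tot = float(np.sum((dT - dT.mean()) ** 2)) if len(dT) > 1 else float(np.sum(dT**2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    basis = Curve1D(grid, basis_values,
                    metadata={"reference_temperature": str(reference_temperature)})
    ref_level = None
    if normalize_window is not None:
        wmask = grid.window(*normalize_window)
        ref_level = float(np.trapezoid(ref_norm.intensity[wmask], grid.q[wmask]))
    return CalibrationModel(basis, float(reference_temperature),
                            tuple(fit_range), min(1.0, r2), ref_level)


def fit_temperature(
    series: DifferenceSeries,
    cal: CalibrationModel,
    fit_range=None,
    baseline_temperature: float | None = None,
    weighted: bool = False,
) -> TemperatureTrace:
    """Retrieve ΔT(t) by projecting each frame onto the calibration basis.

    c(t) = ⟨ΔI(·, t), ΔI_heat⟩ / ⟨ΔI_heat, ΔI_heat⟩ over the fit range;
    with ``weighted=True`` the inner products use 1/σ² weights from the
    series SEM.  Uncertainties are propagated from the per-bin SEM.
    """
    fit_range = tuple(fit_range) if fit_range is not None else cal.fit_range
    mask = series.grid.window(*fit_range)
    if not mask.any():
        raise InvalidArgumentError(
            f"series grid has no points in the fit range {fit_range}"
        )
    if baseline_temperature is not None and \
            abs(baseline_temperature - cal.reference_temperature) > 1e-6:
        warnings.warn(
            f"series baseline {baseline_temperature} °C differs from the "
            f"calibration reference {cal.reference_temperature} °C; the "
            "retrieved ΔT is least accurate in this situation",
            stacklevel=2,
        )
    b = cal.basis_on(series.grid)[mask]
    # match the scan's normalisation reference level to the calibration's
    series_ref = series.metadata.get("normalize_reference")
    if series_ref is not None and cal.reference_level:
        b = b * (float(series_ref) / cal.reference_level)
    data = series.delta_I[:, mask]
    if weighted:
        if series.sem is None:
            raise InvalidArgumentError("weighted fit requires a series with SEM")
        w = 1.0 / np.maximum(series.sem[:, mask], 1e-300) ** 2
        denom = (w * b[None, :] ** 2).sum(axis=1)
        c = (w * data * b[None, :]).sum(axis=1) / denom
        sem = 1.0 / np.sqrt(denom)
    else:
        bb = float(b @ b)
        if bb <= 0:
            raise DegenerateInputError("calibration basis vanishes on the fit range")
        c = data @ b / bb
        sem = None
        if series.sem is not None:
            sem = np.sqrt((series.sem[:, mask] ** 2) @ (b**2)) / bb
    return TemperatureTrace(series.times.copy(), c, c.copy(), sem,
                            metadata={"fit_range": list(fit_range)})


def detectability(
    series_list,
    cal: CalibrationModel,
    n_average: int,
    time_window: tuple[float, float],
    truth: float | None = None,
    tolerance: float = 2.0,
    n_draws: int = 200,
    seed: int = 0,
) -> dict:
    """Distribution of retrieved ΔT when averaging ``n_average`` repeats.

    Repeats are resampled without replacement into groups of ``n_average``,
    each group is averaged, the temperature retrieved, and the plateau mean
    over ``time_window`` recorded.  Reports mean, standard deviation and —
    when ``truth`` is given — the fraction of estimates within ``tolerance``
    °C of it.
    """
    series_list = list(series_list)
    if n_average < 1 or n_average > len(series_list):
        raise InvalidArgumentError(
            f"n_average={n_average} but only {len(series_list)} repeats available"
        )
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_draws):
        idx = rng.choice(len(series_list), size=n_average, replace=False)
        group = average_repeats([series_list[i] for i in idx])
        trace = fit_temperature(group, cal)
        estimates.append(trace.plateau_mean(*time_window))
    estimates = np.asarray(estimates)
    out = {
        "n_average": n_average,
        "n_draws": n_draws,
        "mean": float(estimates.mean()),
        "std": float(estimates.std(ddof=1)) if n_draws > 1 else 0.0,
        "estimates": estimates,
    }
    if truth is not None:
        out["fraction_within"] = float(np.mean(np.abs(estimates - truth) <= tolerance))
        out["truth"] = float(truth)
        out["tolerance"] = float(tolerance)
    return out


class SpatialMap:
    """Bilinear interpolation of retrieved ΔT over a rectangular (y, z) grid."""

    def __init__(self, y: np.ndarray, z: np.ndarray, values: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self._interp = RegularGridInterpolator(
            (self.y, self.z), self.values, method="linear", bounds_error=True
        )

    def __call__(self, y, z):
        try:
            out = self._interp(np.stack(np.broadcast_arrays(
                np.asarray(y, dtype=float), np.asarray(z, dtype=float)), axis=-1))
        except ValueError as exc:
            raise OutOfDomainError(f"query point outside the mapped region: {exc}") from exc
        if np.isscalar(y) and np.isscalar(z):
            return float(np.asarray(out).reshape(-1)[0])
        return out

    def beam_average(self, center: tuple[float, float],
                     size: tuple[float, float] = (160e-6, 140e-6),
                     n_sub: int = 16) -> float:
        """Area-weighted mean ΔT over an X-ray-spot-sized box (midpoint rule)."""
        cy, cz = center
        wy, wz = size
        ys = cy + (np.arange(n_sub) + 0.5) / n_sub * wy - wy / 2
        zs = cz + (np.arange(n_sub) + 0.5) / n_sub * wz - wz / 2
        YY, ZZ = np.meshgrid(ys, zs, indexing="ij")
        return float(np.mean(self(YY, ZZ)))


def spatial_map(grid_points, spacing: float | None = None) -> SpatialMap:
    """Build a bilinear ΔT map from (y, z, ΔT) samples on a rectangular grid.

    ``grid_points`` must cover a complete rectangular lattice (e.g. the
    100 µm survey grid); ``spacing`` is checked against the lattice when
    given.  At least three non-collinear points are required.
    """
    pts = [(float(y), float(z), float(v)) for y, z, v in grid_points]
    if len(pts) < 3:
        raise InvalidArgumentError("need at least 3 grid points")
    ys = np.unique([p[0] for p in pts])
    zs = np.unique([p[1] for p in pts])
    if ys.size < 2 or zs.size < 2:
        raise InvalidArgumentError("grid points are collinear; need a 2D spread")
    if len(pts) != ys.size * zs.size:
        raise InvalidArgumentError(
            f"{len(pts)} points do not form a complete {ys.size}x{zs.size} grid"
        )
    if spacing is not None:
        for axis in (ys, zs):
            if not np.allclose(np.diff(axis), spacing, rtol=1e-6, atol=1e-12):
                raise InvalidArgumentError(
                    f"grid spacing does not match the declared {spacing}"
                )
    values = np.full((ys.size, zs.size), np.nan)
    yi = {v: i for i, v in enumerate(ys)}
    zi = {v: i for i, v in enumerate(zs)}
    for y, z, v in pts:
        values[yi[y], zi[z]] = v
    if np.isnan(values).any():
        raise InvalidArgumentError("duplicate or missing grid points")
    return SpatialMap(ys, zs, values)
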