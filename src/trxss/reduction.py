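"""Difference-scattering reduction.

The interleaved difference protocol is the core of the method's sensitivity:
frame n of the two laser-off steps flanking every laser-on step is averaged
and subtracted from frame n of that on step.  Because the sample is replaced
between steps, the radiation-damage ramp is a function of in-step time only
and cancels frame-by-frame; because the subtraction is interleaved, any
drift linear in step index cancels as well.  Frame-wise normalisation to the
water scattering around the q ≈ 1.5 1/Å isosbestic point removes the
remaining multiplicative drifts (incident flux, sample thickness) exactly,
since a common gain divides out of the normalised frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .datamodel import Curve1D, QGrid, Scan, Step
from .errors import DegenerateInputError, InvalidArgumentError, ValidationError

__all__ = [
    "DifferenceSeries",
    "NORMALIZE_WINDOW",
    "SOLVENT_SCALE_WINDOW",
    "normalize_curve",
    "normalize_scan",
    "difference_protocol",
    "off_off_control",
    "average_repeats",
    "subtract_solvent_heating",
]

NORMALIZE_WINDOW = (1.45, 1.55)       # around the q = 1.5 isosbestic point
SOLVENT_SCALE_WINDOW = (1.9, 2.1)     # solvent-heating scale fit, q ~ 2 1/Å


@dataclass
class DifferenceSeries:
    """Time-resolved difference scattering ΔI(q, t) for one (or averaged) on-step."""

    grid: QGrid
    delta_I: np.ndarray             # (n_frames, n_q)
    times: np.ndarray               # s from step start (exposure start)
    n_repeats: int = 1
    sem: np.ndarray | None = None   # standard error per (frame, bin)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delta_I = np.asarray(self.delta_I, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.delta_I.ndim != 2 or self.delta_I.shape != (self.times.size, len(self.grid)):
            raise ValidationError(
                f"delta_I shape {self.delta_I.shape} inconsistent with "
                f"{self.times.size} times x {len(self.grid)} q bins"
            )
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.delta_I.shape:
                raise ValidationError("sem shape must match delta_I")
            if np.any(self.sem < 0):
                raise ValidationError("sem must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.delta_I.shape[0]


def _window_integral(grid: QGrid, rows: np.ndarray, window) -> np.ndarray:
    mask = grid.window(*window)
    if mask.sum() < 2:
        raise InvalidArgumentError(
            f"normalisation window {window} covers fewer than 2 grid points"
        )
    return np.trapezoid(rows[..., mask], grid.q[mask], axis=-1)


def _jump_ratio(x: np.ndarray, cut: int, half: int = 150) -> float:
    """Multiplicative jump at ``cut`` from local linear fits on either side.

    Linear fits extrapolated to the cut remove the slow common ramp (e.g.
    radiation damage) that a plain ratio of segment means would alias into
    the jump estimate.
    """
    lo = max(0, cut - half)
    hi = min(x.size, cut + half)
    left, right = x[lo:cut], x[cut:hi]
    if left.size < 4 or right.size < 4:
        return float(right.mean() / left.mean())
    tl = np.arange(left.size) - (left.size - 1)   # cut sits at 0
    tr = np.arange(right.size)
    al = np.polynomial.polynomial.polyfit(tl, left, 1)
    ar = np.polynomial.polynomial.polyfit(tr, right, 1)
    return float(ar[0] / al[0])


def _gain_level(x: np.ndarray, jump_nsigma: float = 7.0,
                min_jump: float = 0.01) -> np.ndarray:
    """Estimate the gain-only level of a per-frame integral series.

    Within one step the incident-intensity gain is constant except for a
    possible synchrotron refill jump (several % of the level, ~15 sigma
    above the photon noise of successive integrals).  Jumps are detected
    against a robust MAD-based noise estimate and compounded into a
    piecewise-constant gain; everything else — in particular the common
    radiation-damage ramp, which must survive so frame matching can cancel
    it — is deliberately NOT absorbed into the returned level.
    """
    if x.size < 2:
        return x.copy()
    d = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d)))
    # refill jumps are several % of the level; the absolute floor keeps the
    # detector from triggering on smooth structure in (nearly) noise-free data
    threshold = max(jump_nsigma * sigma, min_jump * abs(float(np.median(x))))
    cuts = np.flatnonzero(np.abs(d) > threshold) + 1
    gain = np.ones_like(x)
    level = 1.0
    prev = 0
    for cut in cuts:
        if cut <= prev:
            continue
        level *= _jump_ratio(x, cut)
        gain[cut:] = level
        prev = cut
    return gain * float((x / gain).mean())


def normalize_curve(curve: Curve1D, reference: float | Curve1D,
                    window=NORMALIZE_WINDOW) -> tuple[Curve1D, float]:
    """Scale a curve so its window integral equals the reference's.

    ``reference`` is either a target integral value or a curve whose own
    window integral defines the target.  Returns (scaled curve, scale factor).
    """
    if isinstance(reference, Curve1D):
        ref_value = float(_window_integral(reference.grid, reference.intensity, window))
    else:
        ref_value = float(reference)
    own = float(_window_integral(curve.grid, curve.intensity, window))
    if own <= 0:
        raise DegenerateInputError(f"window integral {own} is not positive")
    scale = ref_value / own
    out = curve.copy()
    out.intensity *= scale
    if out.sigma is not None:
        out.sigma *= scale
    return out, scale


def normalize_scan(scan: Scan, window=NORMALIZE_WINDOW, mode: str = "step",
                   smooth_frames: int = 101,
                   reference: float | None = None) -> tuple[Scan, np.ndarray]:
    """Normalise a scan to the water scattering around the isosbestic point.

    Per-frame scale factors are ``reference / window integral``.  Three
    estimators of the per-frame integral are available:

    * ``"step"`` (default): a structured model — one gain level per step
      (split at detected synchrotron-refill jumps) times the scan-wide mean
      in-step intensity profile (the radiation-damage ramp, common to every
      step because the sample is replaced between steps).  Averaging over
      all frames of a step and over all steps of the scan makes both factors
      essentially noise-free; raw per-frame scales would instead inject a
      base-spectrum-shaped noise component into every difference frame.
    * ``"smooth"``: per-frame integrals smoothed with a ``smooth_frames``
      running mean (tracks arbitrary smooth drifts, leaves ~10x-suppressed
      slow normalisation noise).
    * ``"frame"``: raw per-frame integrals (noisiest, fully general).

    The reference level defaults to the first laser-off step's mean frame;
    pass an explicit ``reference`` integral to put several scans (or a scan
    and a calibration) on one common scale, which also makes the result
    invariant under a global gain applied to all frames.  Returns
    (normalised scan, scale matrix of shape (n_steps, n_frames)).
    """
    if mode not in ("step", "smooth", "frame"):
        raise InvalidArgumentError("mode must be 'step', 'smooth' or 'frame'")
    ref = float(reference) if reference is not None else float(
        _window_integral(scan.grid, scan.steps[0].frames.mean(axis=0), window))
    if ref <= 0:
        raise DegenerateInputError("reference frame has non-positive window integral")
    n_frames = scan.steps[0].n_frames
    raw = np.stack([np.atleast_1d(_window_integral(scan.grid, s.frames, window))
                    for s in scan.steps])
    if np.any(raw <= 0):
        raise DegenerateInputError("non-positive window integral in at least one frame")
    if mode == "frame":
        estimate = raw
    elif mode == "smooth":
        n = min(smooth_frames, n_frames)
        estimate = np.stack([
            uniform_filter1d(row, size=n, mode="nearest") if n_frames > 1 else row
            for row in raw
        ])
    else:  # structured gain x common-ramp model
        levels = np.stack([_gain_level(row) for row in raw])
        if n_frames > 3 and scan.n_steps > 1:
            # cubic fit: smooth, monotone-ish dose ramps without edge artefacts;
            # off steps only, so the laser-on heating leak stays out of the ramp
            off_rows = [i for i, s in enumerate(scan.steps) if s.laser_state == "off"]
            profile = (raw[off_rows] / levels[off_rows]).mean(axis=0)
            idx = np.arange(n_frames, dtype=float)
            coeff = np.polynomial.polynomial.polyfit(idx, profile, 3)
            ramp = np.polynomial.polynomial.polyval(idx, coeff)
            ramp /= ramp.mean()
        else:
            ramp = np.ones(n_frames)
        estimate = levels * ramp[None, :]
    scales = ref / estimate
    new_steps = []
    for i, step in enumerate(scan.steps):
        new_steps.append(
            Step(step.index, step.laser_state, step.frames * scales[i][:, None],
                 step.frame_times.copy(), step.exposure, step.t0)
        )
    out = Scan(scan.grid, new_steps, scan.scheme, metadata=dict(scan.metadata))
    out.metadata["normalize_window"] = list(window)
    # reference level ties the scan's normalised scale to the calibration's
    out.metadata["normalize_reference"] = ref
    return out, scales


def difference_protocol(scan: Scan, normalize_window=None,
                        normalize_mode: str = "step") -> list[DifferenceSeries]:
    """Interleaved on-minus-off differences, one series per laser-on step.

    For on-step m, ΔI(q, t_n) = on_m[n] - (off_{m-1}[n] + off_{m+1}[n]) / 2,
    frame index matched exactly.  If ``normalize_window`` is given the scan is
    normalised first (see :func:`normalize_scan`).
    """
    if normalize_window is not None:
        scan, _ = normalize_scan(scan, normalize_window, mode=normalize_mode)
    series = []
    for m in range(1, scan.n_steps, 2):
        on = scan.steps[m]
        off_prev, off_next = scan.steps[m - 1], scan.steps[m + 1]
        delta = on.frames - 0.5 * (off_prev.frames + off_next.frames)
        series.append(
            DifferenceSeries(
                scan.grid, delta, on.frame_times.copy(), n_repeats=1,
                metadata={"on_step": m,
                          **{k: scan.metadata[k]
                             for k in ("seed", "deltaT_true", "tau_true",
                                       "normalize_reference", "normalize_window")
                             if k in scan.metadata}},
            )
        )
    if not series:
        raise ValidationError("scan contains no laser-on steps")
    return series


def off_off_control(scan: Scan, normalize_window=None,
                    normalize_mode: str = "step") -> DifferenceSeries:
    """Null control: differences between disjoint successive off-step pairs.

    Pairs off[2j+1] - off[2j] are formed with exact frame matching and
    averaged; the expected mean is zero, and the result serves as an
    empirical noise floor for the SVD analysis.  Disjoint pairs (rather than
    the flanking-average rule) keep the averaged control's noise level an
    honest, independent estimate.
    """
    if normalize_window is not None:
        scan, _ = normalize_scan(scan, normalize_window, mode=normalize_mode)
    offs = scan.off_steps()
    if len(offs) < 3:
        raise InvalidArgumentError(
            f"off-off control needs >= 3 laser-off steps, got {len(offs)}"
        )
    controls = []
    for j in range(len(offs) // 2):
        a, b = offs[2 * j], offs[2 * j + 1]
        controls.append(
            DifferenceSeries(scan.grid, b.frames - a.frames, a.frame_times.copy())
        )
    out = average_repeats(controls) if len(controls) > 1 else controls[0]
    out.metadata["control"] = "off-off"
    return out


def average_repeats(series_list) -> DifferenceSeries:
    """Per-frame, per-bin mean and SEM across repeated difference series."""
    series_list = list(series_list)
    if not series_list:
        raise InvalidArgumentError("no series to average")
    first = series_list[0]
    for s in series_list[1:]:
        if s.delta_I.shape != first.delta_I.shape or not s.grid.same_as(first.grid):
            raise ValidationError("series shapes/grids do not match")
    stack = np.stack([s.delta_I for s in series_list])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    total = sum(s.n_repeats for s in series_list)
    return DifferenceSeries(first.grid, mean, first.times.copy(),
                            n_repeats=total, sem=sem,
                            metadata={"averaged_from": n, **first.metadata})


def subtract_solvent_heating(
    sample: DifferenceSeries,
    solvent: DifferenceSeries,
    scale_window=SOLVENT_SCALE_WINDOW,
    denoise_rank1: bool = True,
) -> tuple[DifferenceSeries, np.ndarray]:
    """Remove the solvent-heating contribution from a sample difference series.

    Per frame t the scalar s(t) minimising ‖sample - s·solvent‖² over the
    scale window (least squares) is fitted and s(t)·solvent subtracted over
    the full q range.  Returns (heat-subtracted series, s(t)).

    A pure-solvent T-jump difference is rank 1 by construction (c(t)·b(q)),
    so with ``denoise_rank1`` the solvent matrix is first truncated to its
    leading SVD component; fitting against the raw noisy solvent would
    otherwise attenuate s(t) (classical noisy-regressor bias).
    """
    if not sample.grid.same_as(solvent.grid):
        raise ValidationError("sample and solvent grids differ")
    if sample.delta_I.shape != solvent.delta_I.shape:
        raise ValidationError("sample and solvent series shapes differ")
    solvent_matrix = solvent.delta_I
    if denoise_rank1 and min(solvent_matrix.shape) >= 2:
        U, S, Vt = np.linalg.svd(solvent_matrix, full_matrices=False)
        solvent_matrix = S[0] * np.outer(U[:, 0], Vt[0])
    mask = sample.grid.window(*scale_window)
    sw = solvent_matrix[:, mask]
    denom = np.einsum("ij,ij->i", sw, sw)
    scale_ref = float(np.mean(np.einsum("ij,ij->i", sample.delta_I[:, mask],
                                        sample.delta_I[:, mask])))
    if np.all(denom <= 1e-12 * max(scale_ref, 1.0)):
        raise DegenerateInputError(
            f"solvent difference signal is ~0 in the scale window {scale_window}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.einsum("ij,ij->i", sample.delta_I[:, mask], sw) / denom
    s = np.where(denom > 0, s, 0.0)
    corrected = sample.delta_I - s[:, None] * solvent_matrix
    sem = sample.sem.copy() if sample.sem is not None else None
    out = DifferenceSeries(sample.grid, corrected, sample.times.copy(),
                           n_repeats=sample.n_repeats, sem=sem,
                           metadata={**sample.metadata,
                                     "solvent_scale_window": list(scale_window)})
    return out, s
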