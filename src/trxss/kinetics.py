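"""SVD decomposition of ΔI(q, t) and exponential kinetics.

The heat-subtracted difference matrix is decomposed by a thin SVD; for a
single structural transition one component dominates, with the q-space
(left) singular vector carrying the spectral shape of the change and the
time-course (right) singular vector its temporal evolution.  The time course
is fitted with one or two rising exponentials A·(1 - exp(-t/τ)) by nonlinear
least squares with multi-start initialisation, t = 0 at the laser pulse.

A fitted τ is an observed relaxation time: with modest temperature jumps the
transition is bidirectional and forward and reverse rates are expected to be
of similar magnitude, so τ should not be read as a forward rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidArgumentError
from .reduction import DifferenceSeries

__all__ = ["SVDResult", "KineticFit", "svd_analysis", "fit_exponentials",
           "model_select"]


@dataclass
class SVDResult:
    """Thin SVD of a difference series, in the field's LSV/RSV convention.

    ``left_vectors[:, k]`` is the k-th q-space singular vector (LSV) on
    ``q``; ``right_vectors[:, k]`` is the k-th unit-norm time course (RSV)
    on ``times``.  Signs are fixed so each LSV's dominant low-q extremum is
    negative (the expansion signature), making results deterministic.
    """

    q: np.ndarray
    times: np.ndarray
    left_vectors: np.ndarray      # (n_q, k)
    singular_values: np.ndarray   # (k,), nonincreasing
    right_vectors: np.ndarray     # (n_t, k)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the (time x q) matrix from the decomposition."""
        return (self.right_vectors * self.singular_values) @ self.left_vectors.T


@dataclass
class KineticFit:
    """One- or two-exponential fit of a time course."""

    n_exp: int
    tau: np.ndarray               # s, ascending
    amplitudes: np.ndarray
    offset: float
    sse: float
    tau_uncertainty: np.ndarray   # 1-sigma from the fit covariance; inf if unidentifiable
    n_points: int
    identifiable: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return 2 * self.n_exp + 1

    def model(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for tau, amp in zip(self.tau, self.amplitudes):
            out += amp * (1.0 - np.exp(-t / tau))
        return out

    def aicc(self) -> float:
        """Corrected Akaike information criterion from the residual SSE."""
        n, k = self.n_points, self.n_params
        if n <= k + 1:
            return np.inf
        sse = max(self.sse, 1e-300)
        return n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def svd_analysis(
    series: DifferenceSeries,
    post_trigger_only: bool = False,
    t0: float = 0.0,
    q_window: tuple[float, float] | None = None,
    n_components: int | None = None,
) -> SVDResult:
    """Thin SVD of the frame-by-q difference matrix.

    With ``post_trigger_only`` frames before ``t0`` (the laser arrival, in
    step time) are dropped; ``q_window`` restricts the decomposition to a
    q sub-range (e.g. the SAXS window for protein kinetics).
    """
    times = series.times
    data = series.delta_I
    if post_trigger_only:
        keep = times >= t0
        times, data = times[keep], data[keep]
    q = series.grid.q
    if q_window is not None:
        mask = series.grid.window(*q_window)
        q, data = q[mask], data[:, mask]
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise InvalidArgumentError(
            f"SVD needs >= 2 frames and >= 2 q bins, got {data.shape}"
        )
    # data rows are frames -> U holds time courses, rows of Vt hold q shapes
    U, S, Vt = np.linalg.svd(data, full_matrices=False)
    if n_components is not None:
        U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    left = Vt.T.copy()
    right = U.copy()
    # deterministic signs: dominant extremum in the lowest-q quartile negative
    low = q <= q[0] + 0.25 * (q[-1] - q[0])
    for k in range(S.size):
        seg = left[low, k] if low.any() else left[:, k]
        ref = seg[np.argmax(np.abs(seg))] if np.any(seg != 0) else 0.0
        if ref > 0:
            left[:, k] *= -1.0
            right[:, k] *= -1.0
    return SVDResult(q.copy(), times.copy(), left, S, right)


def _exp_model(n_exp: int):
    # causal rise: flat at the offset before the pulse (t < 0)
    if n_exp == 1:
        def f(t, a1, tau1, off):
            tc = np.maximum(t, 0.0)
            return off + a1 * (1.0 - np.exp(-tc / tau1))
    else:
        def f(t, a1, tau1, a2, tau2, off):
            tc = np.maximum(t, 0.0)
            return (off + a1 * (1.0 - np.exp(-tc / tau1))
                    + a2 * (1.0 - np.exp(-tc / tau2)))
    return f


def fit_exponentials(
    times,
    values,
    n_exp: int = 1,
    n_starts: int = 8,
) -> KineticFit:
    """Least-squares fit of values(t) = offset + Σ Aᵢ (1 - exp(-t/τᵢ)).

    ``times`` must be strictly increasing with t = 0 at the laser arrival.
    Pre-trigger points (t < 0) may be included: the model is causal, flat at
    the offset before the pulse, so baseline frames pin the offset and
    tighten the τ estimate.  τ starting points span a logarithmic grid from
    the sampling interval to the post-trigger window; the best of all
    converged starts is returned.  Degenerate (flat) data yield amplitude
    ≈ 0 with ``identifiable=False`` and infinite τ uncertainty rather than
    an error.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 4:
        raise InvalidArgumentError("times/values must be equal-length 1D, n >= 4")
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("times must be strictly increasing")
    if n_exp not in (1, 2):
        raise InvalidArgumentError("n_exp must be 1 or 2")

    dt = float(np.median(np.diff(t)))
    window = float(t[-1] - max(t[0], 0.0))
    if window <= 0:
        window = float(t[-1] - t[0])
    span = float(y.max() - y.min())
    scale = span if span > 0 else 1.0
    model = _exp_model(n_exp)

    tau_grid = np.geomspace(max(dt, 1e-12), window, max(n_starts, 2))
    if n_exp == 1:
        starts = [(span, tau, y[0]) for tau in tau_grid]
        lower = [-np.inf, 1e-12, -np.inf]
        upper = [np.inf, np.inf, np.inf]
    else:
        coarse = np.geomspace(max(dt, 1e-12), window, 4)
        starts = [(0.5 * span, ta, 0.5 * span, tb, y[0])
                  for i, ta in enumerate(coarse) for tb in coarse[i + 1:]]
        lower = [-np.inf, 1e-12, -np.inf, 1e-12, -np.inf]
        upper = [np.inf, np.inf, np.inf, np.inf, np.inf]

    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, bounds=(lower, upper),
                                   maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitFailureError(
            f"{n_exp}-exponential fit failed to converge from all "
            f"{len(starts)} starting points (n={t.size}, span={span:g})"
        )
    popt, pcov, sse = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))

    if n_exp == 1:
        amps = np.array([popt[0]])
        taus = np.array([popt[1]])
        tau_err = np.array([perr[1]])
        offset = float(popt[2])
    else:
        order = np.argsort([popt[1], popt[3]])
        amps = np.array([popt[0], popt[2]])[order]
        taus = np.array([popt[1], popt[3]])[order]
        tau_err = np.array([perr[1], perr[3]])[order]
        offset = float(popt[4])

    # unidentifiable: negligible amplitude or unbounded covariance
    identifiable = bool(np.all(np.isfinite(tau_err))
                        and np.all(np.abs(amps) > 1e-6 * scale))
    if not identifiable:
        tau_err = np.full_like(tau_err, np.inf)
    return KineticFit(n_exp=n_exp, tau=taus, amplitudes=amps, offset=offset,
                      sse=sse, tau_uncertainty=tau_err, n_points=t.size,
                      identifiable=identifiable)


def model_select(fits) -> tuple[KineticFit, float]:
    """Pick the fit with the lowest corrected AIC; ties go to fewer parameters.

    Returns (chosen fit, margin), where the margin is the AICc gap to the
    best rejected alternative (inf when only one candidate is supplied).
    """
    fits = list(fits)
    if not fits:
        raise InvalidArgumentError("no fits to select from")
    n = {f.n_points for f in fits}
    if len(n) > 1:
        raise InvalidArgumentError("fits were not computed on identical data")
    ranked = sorted(fits, key=lambda f: (f.aicc(), f.n_params))
    margin = ranked[1].aicc() - ranked[0].aicc() if len(ranked) > 1 else np.inf
    return ranked[0], float(margin)
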