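"""Core data types and plain-text I/O for 1D scattering curves and scans.

A *curve* is one azimuthally integrated scattering pattern I(q) on a fixed
momentum-transfer grid.  A *scan* is the pump-probe acquisition unit: an
ordered sequence of laser-off / laser-on *steps*, each a frame-by-q intensity
matrix recorded while the sample sits still in the beam, with fresh sample
flushed in between steps.  A valid scan alternates off/on and both begins and
ends with an off step, so every on step has two flanking off steps for the
interleaved difference protocol.

File formats (documented bit-exactly in ``docs/formats.md``):

* curve: whitespace-delimited columns ``q I [sigma]`` with ``# key = value``
  header lines carrying metadata;
* scan: one directory holding ``manifest.yaml``, ``qgrid.txt`` and one
  whitespace-delimited frame-matrix file per step.

All q values are in 1/Å, intensities in detector counts per frame, times in
seconds relative to the start of the step the frame belongs to.  Frame
timestamps refer to the exposure *start* (not midpoint) throughout the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .errors import FormatError, InvalidArgumentError, ValidationError
from .timing import TriggerScheme

__all__ = [
    "QGrid",
    "Curve1D",
    "Step",
    "Scan",
    "q_from_angle",
    "d_from_q",
    "read_curve",
    "write_curve",
    "read_scan",
    "write_scan",
]


# ---------------------------------------------------------------------------
# scalar q-space arithmetic
# ---------------------------------------------------------------------------

def q_from_angle(two_theta, wavelength: float):
    """Momentum transfer q = 4π sin(θ) / λ for scattering angle 2θ.

    Parameters
    ----------
    two_theta : float or array
        Full scattering angle 2θ in radians, in [0, π).
    wavelength : float
        X-ray wavelength λ in Å, > 0.

    Returns
    -------
    float or array
        q in 1/Å.
    """
    if wavelength <= 0:
        raise InvalidArgumentError(f"wavelength must be > 0, got {wavelength}")
    tt = np.asarray(two_theta, dtype=float)
    if np.any(tt < 0) or np.any(tt >= math.pi):
        raise InvalidArgumentError("two_theta must lie in [0, pi)")
    q = 4.0 * math.pi * np.sin(tt / 2.0) / wavelength
    return float(q) if np.isscalar(two_theta) else q


def d_from_q(q):
    """Characteristic real-space distance d = 2π/q (Å for q in 1/Å)."""
    qa = np.asarray(q, dtype=float)
    if np.any(qa <= 0):
        raise InvalidArgumentError("q must be > 0")
    d = 2.0 * math.pi / qa
    return float(d) if np.isscalar(q) else d


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QGrid:
    """Strictly increasing momentum-transfer grid, 1/Å."""

    q: np.ndarray
    wavelength: float | None = None

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.ndim != 1 or q.size == 0:
            raise InvalidArgumentError("q grid must be a non-empty 1D array")
        if np.any(q <= 0):
            raise InvalidArgumentError("all q values must be > 0")
        if np.any(np.diff(q) <= 0):
            raise InvalidArgumentError("q grid must be strictly increasing")

    def __len__(self) -> int:
        return self.q.size

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting q in the closed interval [lo, hi]."""
        if hi <= lo:
            raise InvalidArgumentError(f"empty q window [{lo}, {hi}]")
        return (self.q >= lo) & (self.q <= hi)

    def same_as(self, other: "QGrid") -> bool:
        return self.q.shape == other.q.shape and np.array_equal(self.q, other.q)


@dataclass
class Curve1D:
    """One scattering curve I(q) with optional per-bin standard uncertainty."""

    grid: QGrid
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    temperature_label: float | None = None  # °C, for static series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.grid),):
            raise InvalidArgumentError(
                f"intensity length {self.intensity.size} != grid length {len(self.grid)}"
            )
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.intensity.shape:
                raise InvalidArgumentError("sigma length must match grid length")
            if np.any(self.sigma < 0):
                raise InvalidArgumentError("sigma must be >= 0")

    def copy(self) -> "Curve1D":
        return Curve1D(
            self.grid,
            self.intensity.copy(),
            None if self.sigma is None else self.sigma.copy(),
            self.temperature_label,
            dict(self.metadata),
        )


@dataclass
class Step:
    """One laser-off or laser-on step: a frames-by-q intensity matrix."""

    index: int
    laser_state: str                 # "on" | "off"
    frames: np.ndarray               # (n_frames, n_q)
    frame_times: np.ndarray          # s, relative to step start, exposure START
    exposure: float                  # live time per frame, s
    t0: float = 0.0                  # step start, s from scan start

    def __post_init__(self):
        if self.laser_state not in ("on", "off"):
            raise ValidationError(f"laser_state must be 'on'/'off', got {self.laser_state!r}")
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 2:
            raise ValidationError("frames must be a 2D (frame x q) matrix")
        if self.frames.shape[0] != self.frame_times.size:
            raise ValidationError(
                f"step {self.index}: {self.frames.shape[0]} frame rows but "
                f"{self.frame_times.size} frame times"
            )
        dts = np.diff(self.frame_times)
        if self.frame_times.size > 1:
            if np.any(dts <= 0):
                raise ValidationError(f"step {self.index}: frame_times not strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
                raise ValidationError(f"step {self.index}: frame_times not equally spaced")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Scan:
    """Ordered alternating off/on steps sharing one q grid and trigger scheme."""

    grid: QGrid
    steps: list[Step]
    scheme: TriggerScheme
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.steps:
            raise ValidationError("scan has no steps")
        n_frames = self.steps[0].n_frames
        for i, step in enumerate(self.steps):
            expected = "off" if i % 2 == 0 else "on"
            if step.laser_state != expected:
                raise ValidationError(
                    f"step {i}: laser_state {step.laser_state!r} breaks off/on "
                    f"alternation (expected {expected!r})"
                )
            if step.frames.shape[1] != len(self.grid):
                raise ValidationError(
                    f"step {i}: {step.frames.shape[1]} q bins != grid length {len(self.grid)}"
                )
            if step.n_frames != n_frames:
                raise ValidationError(
                    f"step {i}: {step.n_frames} frames != {n_frames} in step 0"
                )
        if self.steps[-1].laser_state != "off":
            raise ValidationError(
                f"scan must end with a laser-off step (step {len(self.steps) - 1} is on)"
            )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def on_steps(self) -> list[Step]:
        return [s for s in self.steps if s.laser_state == "on"]

    def off_steps(self) -> list[Step]:
        return [s for s in self.steps if s.laser_state == "off"]

    def iter_frames(self) -> Iterator[tuple[int, int, np.ndarray]]:
        """Yield (step_index, frame_index, intensity_row) over the whole scan."""
        for i, step in enumerate(self.steps):
            for n in range(step.n_frames):
                yield i, n, step.frames[n]


# ---------------------------------------------------------------------------
# curve file I/O
# ---------------------------------------------------------------------------

_FLOAT_KEYS = {"temperature", "exposure", "wavelength", "t0"}


def _format_float(x: float) -> str:
    return repr(float(x))


def write_curve(curve: Curve1D, path) -> None:
    """Write a curve as whitespace-delimited text with '# key = value' header."""
    path = Path(path)
    lines = ["# trxss-curve"]
    meta = dict(curve.metadata)
    if curve.temperature_label is not None:
        meta["temperature"] = curve.temperature_label
    if curve.grid.wavelength is not None:
        meta["wavelength"] = curve.grid.wavelength
    for key in sorted(meta):
        lines.append(f"# {key} = {meta[key]}")
    has_sigma = curve.sigma is not None
    lines.append("# columns = q I sigma" if has_sigma else "# columns = q I")
    for i, q in enumerate(curve.grid.q):
        row = [_format_float(q), _format_float(curve.intensity[i])]
        if has_sigma:
            row.append(_format_float(curve.sigma[i]))
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_curve(path) -> Curve1D:
    """Read a curve written by :func:`write_curve` (2 or 3 numeric columns)."""
    path = Path(path)
    meta: dict = {}
    q, inten, sig = [], [], []
    ncols = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                value = value.strip()
                if key and key not in ("columns",):
                    meta[key] = float(value) if key in _FLOAT_KEYS else value
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise FormatError(f"expected 2 or 3 columns, got {len(parts)}", path, lineno)
        if ncols is None:
            ncols = len(parts)
        elif len(parts) != ncols:
            raise FormatError("ragged columns", path, lineno)
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise FormatError(f"non-numeric value in {parts!r}", path, lineno) from None
        q.append(vals[0])
        inten.append(vals[1])
        if ncols == 3:
            sig.append(vals[2])
        if len(q) > 1 and q[-1] <= q[-2]:
            raise FormatError(f"q not strictly increasing at q={q[-1]}", path, lineno)
    if not q:
        raise FormatError("no data rows", path)
    temperature = meta.pop("temperature", None)
    wavelength = meta.pop("wavelength", None)
    grid = QGrid(np.asarray(q), wavelength=wavelength)
    sigma = np.asarray(sig) if ncols == 3 else None
    return Curve1D(grid, np.asarray(inten), sigma, temperature, meta)


# ---------------------------------------------------------------------------
# scan container I/O
# ---------------------------------------------------------------------------

def write_scan(scan: Scan, directory) -> None:
    """Write a scan as manifest.yaml + qgrid.txt + one frame matrix per step."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "qgrid.txt", scan.grid.q, fmt="%.17g")
    records = []
    for step in scan.steps:
        fname = f"step_{step.index:04d}.txt"
        np.savetxt(directory / fname, step.frames, fmt="%.17g")
        records.append(
            {
                "index": step.index,
                "laser_state": step.laser_state,
                "frames_file": fname,
                "t0": float(step.t0),
                "exposure": float(step.exposure),
                "frame_period": float(np.diff(step.frame_times)[0])
                if step.n_frames > 1
                else 1.0 / scan.scheme.frame_rate,
            }
        )
    manifest = {
        "format": "trxss-scan",
        "scheme": scan.scheme.to_dict(),
        "metadata": scan.metadata,
        "steps": records,
    }
    if scan.grid.wavelength is not None:
        manifest["wavelength"] = scan.grid.wavelength
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
    )


def read_scan(directory) -> Scan:
    """Read a scan directory written by :func:`write_scan`; validates invariants."""
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise FormatError("missing manifest.yaml", directory)
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict) or manifest.get("format") != "trxss-scan":
        raise FormatError("not a trxss-scan manifest", manifest_path)
    scheme = TriggerScheme.from_dict(manifest["scheme"])
    q = np.loadtxt(directory / "qgrid.txt", ndmin=1)
    grid = QGrid(q, wavelength=manifest.get("wavelength"))
    steps = []
    for rec in manifest["steps"]:
        frames = np.loadtxt(directory / rec["frames_file"], ndmin=2)
        period = float(rec.get("frame_period", 1.0 / scheme.frame_rate))
        times = np.arange(frames.shape[0]) * period
        steps.append(
            Step(
                index=int(rec["index"]),
                laser_state=rec["laser_state"],
                frames=frames,
                frame_times=times,
                exposure=float(rec.get("exposure", scheme.frame_live_time())),
                t0=float(rec.get("t0", 0.0)),
            )
        )
    return Scan(grid, steps, scheme, metadata=manifest.get("metadata", {}))
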