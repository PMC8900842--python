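"""End-to-end orchestration: simulate -> reduce -> calibrate -> thermometry -> kinetics.

A pipeline run is driven by one declarative config (a nested dict, usually
loaded from YAML); the same config plus the same seed produces the same
report.  Every artefact written to disk carries the config hash and seed in
its metadata, and the report collects the headline scalars: the retrieved
temperature jump, the exponential time constants, and the leading
singular-value spectrum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import yaml

from . import kinetics, reduction, synthetic, thermometry
from .datamodel import Scan, write_curve, write_scan
from .errors import ConfigError
from .timing import TriggerScheme

__all__ = ["default_config", "config_hash", "run_pipeline", "make_fixtures"]

log = logging.getLogger("trxss.pipeline")

SAXS_WINDOW = (0.0, 1.0)   # protein kinetics q range (low-q side of the grid)


def default_config(seed: int = 0) -> dict:
    """Demo configuration mirroring the standard acquisition protocol."""
    return {
        "seed": seed,
        "scheme": TriggerScheme(train_duration=3.0).to_dict(),
        "noise": {
            "flux": 1e12,
            "drift_amplitude": 0.10,
            "injection_period": 600.0,
            "damage_slope": 0.01,
            "poisson": True,
        },
        "truth": {
            "deltaT": 13.1,
            "tau": [4.46],
            "amplitudes": [1.0],
            "maintained": True,
            "cooling_tau": 0.2,
        },
        "n_steps": 21,
        "baseline_temperature": 20.0,
        "reduction": {
            "normalize_window": list(reduction.NORMALIZE_WINDOW),
            "solvent_scale_window": list(reduction.SOLVENT_SCALE_WINDOW),
            "subtract_solvent": True,
        },
        "calibration": {
            "temperatures": [20.0, 25.0, 30.0, 35.0, 40.0],
            "reference": 20.0,
            "n_frames": 1000,
            "fit_range": list(thermometry.WAXS_FIT_RANGE),
        },
        "kinetics": {
            "n_exp": "auto",
            "q_window": list(SAXS_WINDOW),
            "plateau": [0.2, 2.8],
        },
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _require(config: dict, key: str):
    if key not in config:
        raise ConfigError(f"pipeline config is missing the {key!r} section")
    return config[key]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: dict, workdir=None) -> dict:
    """Execute all stages in order and return the summary report.

    With ``workdir`` set, per-stage artefacts (scan directories, calibration
    basis, report) are written there; stage failures propagate with already
    written artefacts left in place for inspection.
    """
    t_start = _time.monotonic()
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    scheme = TriggerScheme.from_dict(_require(config, "scheme"))
    noise_cfg = _require(config, "noise")
    truth_cfg = _require(config, "truth")
    red_cfg = _require(config, "reduction")
    cal_cfg = _require(config, "calibration")
    kin_cfg = _require(config, "kinetics")
    subtract_solvent = bool(red_cfg.get("subtract_solvent", True))

    s_scan, s_solvent, s_static = _child_seeds(seed, 3)
    truth = synthetic.KineticTruth(
        tau=tuple(truth_cfg["tau"]),
        amplitudes=tuple(truth_cfg["amplitudes"]),
        deltaT_true=float(truth_cfg["deltaT"]),
        maintained=bool(truth_cfg.get("maintained", True)),
        cooling_tau=float(truth_cfg.get("cooling_tau", 0.2)),
    )

    def _noise(child_seed):
        return synthetic.NoiseConfig(
            flux=float(noise_cfg.get("flux", 1e12)),
            drift_amplitude=float(noise_cfg.get("drift_amplitude", 0.10)),
            injection_period=float(noise_cfg.get("injection_period", 600.0)),
            damage_slope=float(noise_cfg.get("damage_slope", 0.01)),
            seed=child_seed,
            poisson=bool(noise_cfg.get("poisson", True)),
        )

    def _stage(name):
        log.info("stage %-16s starting", name)
        return _time.monotonic()

    def _done(name, t0, **scalars):
        pretty = " ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                          for k, v in scalars.items())
        log.info("stage %-16s done in %.2f s %s", name, _time.monotonic() - t0, pretty)

    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ----------------------------------------------------------
    t0 = _stage("simulate")
    n_steps = int(config.get("n_steps", 21))
    scan = synthetic.simulate_scan(
        scheme, truth, _noise(s_scan), n_steps=n_steps,
        baseline_temperature=float(config.get("baseline_temperature", 20.0)),
    )
    solvent_scan = None
    if subtract_solvent:
        solvent_scan = synthetic.simulate_solvent_scan(
            scheme, truth.deltaT_true, _noise(s_solvent), n_steps=n_steps,
            maintained=truth.maintained, cooling_tau=truth.cooling_tau,
        )
    for s in filter(None, [scan, solvent_scan]):
        s.metadata.update(config_hash=chash, pipeline_seed=seed)
    if workdir is not None:
        write_scan(scan, workdir / "scan_sample")
        if solvent_scan is not None:
            write_scan(solvent_scan, workdir / "scan_solvent")
    _done("simulate", t0, steps=n_steps)

    # --- reduce ------------------------------------------------------------
    t0 = _stage("reduce")
    window = tuple(red_cfg.get("normalize_window", reduction.NORMALIZE_WINDOW))
    series = reduction.difference_protocol(scan, normalize_window=window)
    averaged = reduction.average_repeats(series)
    solvent_scale = None
    if subtract_solvent:
        sol_series = reduction.difference_protocol(solvent_scan, normalize_window=window)
        sol_avg = reduction.average_repeats(sol_series)
        heat_free, solvent_scale = reduction.subtract_solvent_heating(
            averaged, sol_avg,
            scale_window=tuple(red_cfg.get("solvent_scale_window",
                                           reduction.SOLVENT_SCALE_WINDOW)),
        )
    else:
        heat_free = averaged
    _done("reduce", t0, repeats=averaged.n_repeats)

    # --- calibrate ---------------------------------------------------------
    t0 = _stage("calibrate")
    static = synthetic.simulate_static_series(
        cal_cfg["temperatures"], float(cal_cfg["reference"]), _noise(s_static),
        n_frames=int(cal_cfg.get("n_frames", 1000)),
    )
    cal = thermometry.calibrate(
        static, float(cal_cfg["reference"]),
        fit_range=tuple(cal_cfg.get("fit_range", thermometry.WAXS_FIT_RANGE)),
        normalize_window=window,
    )
    if workdir is not None:
        cal.basis.metadata.update(config_hash=chash, seed=str(seed))
        write_curve(cal.basis, workdir / "calibration_basis.txt")
    _done("calibrate", t0, r2=cal.linearity_r2)

    # --- fit temperature ---------------------------------------------------
    t0 = _stage("fit-temperature")
    trace = thermometry.fit_temperature(
        averaged, cal, baseline_temperature=float(config.get("baseline_temperature", 20.0)),
    )
    plateau = kin_cfg.get("plateau", [0.2, 2.8])
    retrieved_dT = trace.plateau_mean(scheme.dt1 + plateau[0], scheme.dt1 + plateau[1])
    _done("fit-temperature", t0, deltaT=retrieved_dT)

    # --- kinetics ----------------------------------------------------------
    t0 = _stage("kinetics")
    q_window = tuple(kin_cfg.get("q_window", SAXS_WINDOW))
    # full-step SVD: pre-trigger frames carry the baseline for the causal fit
    svd = kinetics.svd_analysis(heat_free, q_window=q_window)
    rsv_times = svd.times - scheme.dt1
    rsv = svd.right_vectors[:, 0] * svd.singular_values[0]
    n_exp_req = kin_cfg.get("n_exp", "auto")
    if n_exp_req == "auto":
        fits = [kinetics.fit_exponentials(rsv_times, rsv, n_exp=k) for k in (1, 2)]
        fit, margin = kinetics.model_select(fits)
    else:
        fit = kinetics.fit_exponentials(rsv_times, rsv, n_exp=int(n_exp_req))
        margin = np.inf
    _done("kinetics", t0, n_exp=fit.n_exp, tau=float(fit.tau[-1]))

    report = {
        "config_hash": chash,
        "seed": seed,
        "truth": {"deltaT": truth.deltaT_true, "tau": list(truth.tau)},
        "retrieved_deltaT": float(retrieved_dT),
        "tau": [float(t) for t in fit.tau],
        "tau_uncertainty": [float(u) for u in fit.tau_uncertainty],
        "n_exp": int(fit.n_exp),
        "model_margin": float(margin),
        "calibration_r2": float(cal.linearity_r2),
        "singular_values": [float(s) for s in svd.singular_values[:5]],
        "n_repeats": int(averaged.n_repeats),
        "solvent_scale_mean": float(np.mean(solvent_scale))
        if solvent_scale is not None else None,
        "wall_time_s": float(_time.monotonic() - t_start),
    }
    if workdir is not None:
        (workdir / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=True))
    return report


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the small deterministic fixture set used by tests and examples.

    A coarse q grid and a short 5-step scan keep every file small and
    byte-stable for a given seed.  Returns the paths written plus the truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = TriggerScheme(frame_rate=500.0, readout_dead_time=100e-6,
                           step_duration=0.2, dt1=0.05, tw1=2e-3,
                           train_duration=0.0)
    grid = synthetic.default_grid(saxs_step=0.05, waxs_step=0.05)
    truth = synthetic.KineticTruth(tau=(0.05,), amplitudes=(1.0,),
                                   deltaT_true=10.0, maintained=False,
                                   cooling_tau=0.2)
    s_scan, s_static = _child_seeds(seed, 2)
    noise = synthetic.NoiseConfig(seed=s_scan)
    scan = synthetic.simulate_scan(scheme, truth, noise, n_steps=5, grid=grid)
    write_scan(scan, out_dir / "scan_small")
    static = synthetic.simulate_static_series(
        [20.0, 30.0, 40.0], 20.0, synthetic.NoiseConfig(seed=s_static),
        grid=grid, n_frames=200,
    )
    for curve in static:
        write_curve(curve, out_dir / f"static_{curve.temperature_label:.0f}C.txt")
    truth_doc = {
        "seed": seed,
        "deltaT": truth.deltaT_true,
        "tau": list(truth.tau),
        "amplitudes": list(truth.amplitudes),
        "maintained": truth.maintained,
        "cooling_tau": truth.cooling_tau,
        "scheme": scheme.to_dict(),
    }
    (out_dir / "truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=True))
    return {"scan": out_dir / "scan_small", "truth": truth_doc,
            "static": sorted(out_dir.glob("static_*.txt"))}
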