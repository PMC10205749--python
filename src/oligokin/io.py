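"""File formats, pipeline configuration and the end-to-end pipeline.

All tabular data are CSV, all structured outputs JSON.  Traces are CSV
with a ``time_s,signal_V`` header; trajectories are CSV with columns
``time_s, c_1 .. c_Nmax, overflow_mM`` plus a JSON metadata sidecar;
spectra are a raw whitespace-delimited matrix with a JSON header sidecar
describing the ppm axes and noise level.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import coagulation as coag
from . import fitting
from .nmr import Spectrum2D
from .scattering import KineticTrace, calibrate_from_monomer
from .synthetic import NoiseModel, gen_stretched_trace

logger = logging.getLogger("oligokin")

__all__ = [
    "read_trace",
    "write_trace",
    "read_trajectory",
    "write_trajectory",
    "read_spectrum",
    "write_spectrum",
    "PipelineConfig",
    "run_pipeline",
]


class TraceFormatError(ValueError):
    """Malformed trace file."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: KineticTrace, path) -> None:
    """Write a trace as ``time_s,signal_V`` CSV with a JSON sidecar for the
    background level and metadata."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.t, "signal_V": trace.y}).to_csv(
        path, index=False, float_format="%.10g"
    )
    meta = {"label": trace.label, "background_V": trace.background, **trace.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))


def read_trace(path) -> KineticTrace:
    """Read a ``time_s,signal_V`` CSV trace; validates monotone times and
    reports malformed rows with their line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file") from exc
    for col in ("time_s", "signal_V"):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing column {col!r}")
    for col in ("time_s", "signal_V"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if bad.size:
            raise TraceFormatError(
                f"{path}: non-numeric {col!r} at line {bad[0] + 2}"  # header + 1-based
            )
    t = df["time_s"].to_numpy(dtype=float)
    y = df["signal_V"].to_numpy(dtype=float)
    dec = np.nonzero(np.diff(t) < 0)[0]
    if dec.size:
        raise TraceFormatError(f"{path}: time decreases at line {dec[0] + 3}")
    background = None
    label = ""
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        background = meta.pop("background_V", None)
        label = meta.pop("label", "")
    return KineticTrace(t, y, background=background, label=label, meta=meta)


def write_trajectory(traj: coag.Trajectory, path) -> None:
    """Trajectory CSV (time_s, c_1..c_Nmax, overflow_mM) + JSON sidecar."""
    path = Path(path)
    cols = {"time_s": traj.times}
    for i in range(traj.nmax):
        cols[f"c_{i + 1}"] = traj.concentrations[:, i]
    cols["overflow_mM"] = traj.overflow
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
    _sidecar(path).write_text(json.dumps(traj.meta, indent=1, default=str))


def read_trajectory(path) -> coag.Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    nmax = sum(1 for c in df.columns if c.startswith("c_"))
    c = df[[f"c_{i + 1}" for i in range(nmax)]].to_numpy(dtype=float)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return coag.Trajectory(
        df["time_s"].to_numpy(dtype=float),
        c,
        df["overflow_mM"].to_numpy(dtype=float),
        meta,
    )


def write_spectrum(spec: Spectrum2D, path) -> None:
    """Raw matrix (whitespace-delimited text) + JSON header sidecar with
    axis start/step/count and noise level."""
    path = Path(path)
    np.savetxt(path, spec.intensity, fmt="%.8g")
    header = {
        "axis1": {
            "start_ppm": float(spec.axis1[0]),
            "step_ppm": float(spec.step[0]),
            "count": int(spec.axis1.size),
        },
        "axis2": {
            "start_ppm": float(spec.axis2[0]),
            "step_ppm": float(spec.step[1]),
            "count": int(spec.axis2.size),
        },
        "noise_rms": spec.noise_rms,
        "label": spec.label,
    }
    _sidecar(path).write_text(json.dumps(header, indent=1))


def read_spectrum(path) -> Spectrum2D:
    path = Path(path)
    header = json.loads(_sidecar(path).read_text())
    intensity = np.loadtxt(path)
    axes = []
    for key in ("axis1", "axis2"):
        h = header[key]
        axes.append(h["start_ppm"] + h["step_ppm"] * np.arange(h["count"]))
    return Spectrum2D(
        axes[0], axes[1], intensity, noise_rms=header.get("noise_rms", 0.0),
        label=header.get("label", ""),
    )


# ---------------------------------------------------------------------------
# Pipeline configuration


class KernelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r0: float = Field(gt=0)
    e0: float = Field(default=1.0, ge=1)
    nth: float = Field(default=16.0, gt=0)


class TargetConfig(BaseModel):
    """Empirical composite target curve (V above background)."""

    model_config = ConfigDict(extra="forbid")
    a1: float = 0.015
    b1: float = 0.1147
    tau1: float = 0.141
    beta1: float = 0.540
    a2: float = 0.00036057
    b2: float = 0.43465
    tau2: float = 176.0
    beta2: float = 0.6127


class ScanConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nth_grid: list[float] = Field(default=[2, 4, 8, 16, 32, 64], min_length=1)
    c0_mm: float = Field(default=1.5, gt=0)
    monomer_signal_v: float = Field(default=0.015, gt=0)
    monomer_conc_mm: float = Field(default=1.5, gt=0)


class SynthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_v: float = Field(default=0.002, ge=0)
    replicates: int = Field(default=6, ge=1)
    t_end_s: float = Field(default=0.5, gt=0)
    dt_s: float = Field(default=0.25e-3, gt=0)


class PipelineConfig(BaseModel):
    """Validated configuration of the synth -> fit -> scan pipeline.

    Unknown keys are rejected; the JSON schema is available from
    ``PipelineConfig.model_json_schema()``.
    """

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    target: TargetConfig = TargetConfig()
    scan: ScanConfig = ScanConfig()
    synth: SynthConfig = SynthConfig()
    stages: list[str] = Field(default=["synth", "fit", "scan"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return a JSON-ready report.

    Stages: ``synth`` generates a noisy short-time trace from the target's
    short-time block and refits it; ``fit`` optimizes (r0, E0) at the middle
    of the Nth grid; ``scan`` re-optimizes across the grid.  Any stage
    failure propagates as an exception (non-zero CLI exit).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tc = config.target
    base = fitting.StretchedExpParams(a1=tc.a1, b1=tc.b1, tau1=tc.tau1, beta1=tc.beta1)
    target = fitting.CompositeParams(
        base=base, a2=tc.a2, b2=tc.b2, tau2=tc.tau2, beta2=tc.beta2
    )
    cal = calibrate_from_monomer(
        config.scan.monomer_signal_v, config.scan.monomer_conc_mm
    )
    report: dict = {
        "config": config.model_dump(),
        "versions": {"oligokin": _version()},
    }

    if "synth" in config.stages:
        logger.info("stage synth: generating and refitting a short-time trace")
        grid = config.synth.dt_s * np.arange(
            1, int(round(config.synth.t_end_s / config.synth.dt_s)) + 1
        )
        noise = NoiseModel(
            sigma=config.synth.sigma_v, replicates=config.synth.replicates, seed=config.seed
        )
        trace = gen_stretched_trace(base, grid, noise)
        write_trace(trace, outdir / "synthetic_short_time.csv")
        refit = fitting.fit_stretched(trace, fixed_a1=base.a1)
        report["synth"] = {
            "true": {"a1": base.a1, "b1": base.b1, "tau1_s": base.tau1, "beta1": base.beta1},
            "refit": {
                "b1": refit.b1,
                "tau1_s": refit.tau1,
                "beta1": refit.beta1,
                "stderr": refit.stderr,
            },
            "seed": config.seed,
        }

    if "fit" in config.stages:
        grid_nth = config.scan.nth_grid
        nth0 = grid_nth[len(grid_nth) // 2]
        logger.info("stage fit: optimizing (r0, E0) at Nth=%s", nth0)
        fit = fitting.fit_coagulation(target, nth0, c0=config.scan.c0_mm, cal=cal)
        report["fit"] = {
            "nth": fit.nth,
            "r0_mM-1s-1": fit.r0,
            "e0": fit.e0,
            "s2": fit.s2,
            "boundary_flags": fit.boundary_flags,
        }

    if "scan" in config.stages:
        logger.info("stage scan: Nth grid %s", config.scan.nth_grid)
        scan = fitting.scan_nth(target, config.scan.nth_grid, c0=config.scan.c0_mm, cal=cal)
        report["scan"] = {
            "per_nth": scan.per_nth.to_dict(orient="records"),
            "best_nth": scan.best_nth,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("oligokin")
    except Exception:
        return "unknown"
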