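"""Seeded generators of synthetic stopped-flow traces and 2D spectra.

These emulate the statistical structure of the instruments the analysis
consumes: photomultiplier traces sampled at 0.25 ms with additive Gaussian
noise on a constant solvent background (replicate averaging reduces the
noise by sqrt(R)), and 2D spectra built from Gaussian crosspeaks with
FWHM linewidths in the 2-7 ppm range typical of frozen-solution data.
Generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coagulation as coag
from .fitting import (
    StretchedExpParams,
    ThTParams,
    eval_stretched,
    eval_tht,
)
from .nmr import Spectrum2D
from .scattering import KineticTrace, ScatterCalibration, forward_signal

__all__ = [
    "NoiseModel",
    "GaussianPeak",
    "gen_scattering_trace",
    "gen_stretched_trace",
    "gen_spectrum",
    "stopped_flow_grid",
    "FWHM_TO_SIGMA",
]

#: Gaussian FWHM = 2 sqrt(2 ln 2) sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Fastest sampling interval of the stopped-flow instrument, s.
STOPPED_FLOW_DT = 0.25e-3


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with replicate averaging.

    ``sigma`` is the per-replicate standard deviation (V for traces,
    intensity units for spectra); the recorded noise level after averaging
    ``replicates`` acquisitions is ``sigma / sqrt(replicates)``.
    """

    sigma: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def effective_sigma(self) -> float:
        return self.sigma / np.sqrt(self.replicates)

    def sample(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.zeros(shape)
        reps = rng.normal(0.0, self.sigma, size=(self.replicates, *np.atleast_1d(shape)))
        return reps.mean(axis=0).reshape(shape)


def stopped_flow_grid(t_end: float = 0.5, dt: float = STOPPED_FLOW_DT) -> np.ndarray:
    """Acquisition grid (0, t_end] at the instrument sampling interval."""
    n = int(round(t_end / dt))
    return dt * np.arange(1, n + 1)


def gen_scattering_trace(
    params: coag.KernelParams,
    c0: float,
    cal: ScatterCalibration,
    sampling: np.ndarray,
    noise: NoiseModel = NoiseModel(),
    *,
    nmax: int = coag.DEFAULT_NMAX,
) -> KineticTrace:
    """Simulated light-scattering trace: coagulation forward model plus
    averaged Gaussian noise.  Deterministic given the seed."""
    sampling = np.asarray(sampling, dtype=float)
    init = coag.monomer_distribution(c0, nmax)
    traj = coag.simulate_coagulation(init, params, sampling)
    trace = forward_signal(traj, cal, label=f"synthetic scattering c0={c0} mM")
    rng = np.random.default_rng(noise.seed)
    trace.y = trace.y + noise.sample(trace.y.shape, rng)
    trace.meta.update(
        {
            "generator": "gen_scattering_trace",
            "kernel": {"r0": params.r0, "e0": params.e0, "nth": params.nth},
            "c0_mM": c0,
            "noise_sigma_V": noise.sigma,
            "replicates": noise.replicates,
            "seed": noise.seed,
        }
    )
    return trace


def gen_stretched_trace(
    params: StretchedExpParams | ThTParams,
    grid: np.ndarray,
    noise: NoiseModel = NoiseModel(),
    background: float = 0.0,
) -> KineticTrace:
    """Trace from a stretched-exponential form plus averaged Gaussian noise.

    Accepts either the scattering parameterization (signal above
    background) or the ThT fluorescence one.
    """
    grid = np.asarray(grid, dtype=float)
    if isinstance(params, ThTParams):
        y = eval_tht(params, grid)
    else:
        y = eval_stretched(params, grid)
    rng = np.random.default_rng(noise.seed)
    y = y + background + noise.sample(y.shape, rng)
    return KineticTrace(
        grid.copy(),
        y,
        background=background,
        label="synthetic stretched-exponential",
        meta={
            "generator": "gen_stretched_trace",
            "noise_sigma": noise.sigma,
            "replicates": noise.replicates,
            "seed": noise.seed,
        },
    )


@dataclass(frozen=True)
class GaussianPeak:
    """2D Gaussian crosspeak with FWHM linewidths.

    ``amplitude`` is the peak height; ``volume`` converts via
    ``height * 2 pi sigma1 sigma2``.
    """

    center1: float  # ppm
    center2: float  # ppm
    fwhm1: float  # ppm
    fwhm2: float  # ppm
    amplitude: float = 1.0

    @property
    def volume(self) -> float:
        s1 = self.fwhm1 * FWHM_TO_SIGMA
        s2 = self.fwhm2 * FWHM_TO_SIGMA
        return self.amplitude * 2.0 * np.pi * s1 * s2

    @classmethod
    def from_volume(
        cls, center1: float, center2: float, fwhm1: float, fwhm2: float, volume: float
    ) -> "GaussianPeak":
        s1 = fwhm1 * FWHM_TO_SIGMA
        s2 = fwhm2 * FWHM_TO_SIGMA
        return cls(center1, center2, fwhm1, fwhm2, volume / (2.0 * np.pi * s1 * s2))

    def evaluate(self, ppm1: np.ndarray, ppm2: np.ndarray) -> np.ndarray:
        s1 = self.fwhm1 * FWHM_TO_SIGMA
        s2 = self.fwhm2 * FWHM_TO_SIGMA
        g1 = np.exp(-0.5 * ((ppm1 - self.center1) / s1) ** 2)
        g2 = np.exp(-0.5 * ((ppm2 - self.center2) / s2) ** 2)
        return self.amplitude * np.outer(g1, g2)


def gen_spectrum(
    peaks,
    axis1: np.ndarray,
    axis2: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    label: str = "",
) -> Spectrum2D:
    """Sum of 2D Gaussian crosspeaks plus seeded Gaussian noise.

    ``peaks`` is a sequence of ``GaussianPeak`` or ``(center1, center2,
    fwhm1, fwhm2, amplitude)`` tuples.  The recorded ``noise_rms`` is the
    true effective noise level of the generated spectrum.
    """
    peaks = list(peaks)
    axis1 = np.asarray(axis1, dtype=float)
    axis2 = axis1.copy() if axis2 is None else np.asarray(axis2, dtype=float)
    intensity = np.zeros((axis1.size, axis2.size))
    for pk in peaks:
        if not isinstance(pk, GaussianPeak):
            pk = GaussianPeak(*pk)
        intensity += pk.evaluate(axis1, axis2)
    rng = np.random.default_rng(noise.seed)
    intensity += noise.sample(intensity.shape, rng)
    return Spectrum2D(
        axis1,
        axis2,
        intensity,
        noise_rms=noise.effective_sigma,
        label=label or "synthetic spectrum",
        meta={"generator": "gen_spectrum", "seed": noise.seed, "n_peaks": len(peaks)},
    )
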