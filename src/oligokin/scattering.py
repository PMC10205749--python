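"""Static light scattering observables for oligomer distributions.

For a mixture of n-mers with monomer-equivalent mass concentrations
``c_n(t)``, the 90-degree scattering signal recorded as a photomultiplier
voltage is

    S(t) = S_b + k * M_w * sum_n c_n(t) * n,

with ``S_b`` the solvent background, ``M_w`` the monomer molecular weight
(4.33 kDa for the 40-residue amyloid-beta peptide) and ``k`` an instrument
constant.  Hence ``S(t) - S_b`` is proportional to the mass-weighted mean
size ``n_ave(t)``: complete conversion of monomers to octamers multiplies
the signal above background by exactly eight.

This deliberately ignores refractive-index-increment variations with
oligomer size, the second virial coefficient and particle form factors;
for globular particles much smaller than the illumination wavelength these
corrections are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coagulation import Trajectory

__all__ = [
    "ScatterCalibration",
    "KineticTrace",
    "forward_signal",
    "calibrate_from_monomer",
    "calibrate_from_standards",
    "n_ave_from_signal",
    "sphere_volume",
    "sphere_diameter",
    "assembly_diameter",
    "MW_AB40_KDA",
    "DEFAULT_PROTEIN_DENSITY",
]

#: Molecular weight of the Abeta40 monomer, kDa.
MW_AB40_KDA = 4.33
#: Typical protein partial specific density, g/cm^3.
DEFAULT_PROTEIN_DENSITY = 1.35

_KDA_TO_G = 1.66053906660e-21  # 1 kDa in grams (1000 u)


@dataclass(frozen=True)
class ScatterCalibration:
    """Instrument calibration mapping mass-weighted concentration to volts.

    ``k`` is the signal per mM.kDa of the mass-weighted product
    ``M_w * sum(c_n n)``; ``s_b`` is the solvent background voltage.
    """

    s_b: float  # V
    k: float  # V / (mM kDa)
    m_w: float = MW_AB40_KDA  # kDa

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.m_w <= 0:
            raise ValueError("M_w must be > 0")

    def monomer_signal(self, conc: float) -> float:
        """Signal above background from pure monomers at ``conc`` mM."""
        return self.k * self.m_w * conc


@dataclass
class KineticTrace:
    """Time/signal pairs (s, V) with an optional background level."""

    t: np.ndarray
    y: np.ndarray
    background: float | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be equal-length 1-D arrays")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return self.t.size


def forward_signal(traj: Trajectory, cal: ScatterCalibration, label: str = "") -> KineticTrace:
    """Scattering trace predicted for a coagulation trajectory.

    The overflow bin contributes with size ``N_max`` (a conservative
    underestimate of its true scattering; flagged in the trajectory metadata
    when the overflow fraction is significant).
    """
    sizes = np.arange(1, traj.nmax + 1)
    mass_weighted = traj.concentrations @ sizes + traj.overflow * traj.nmax
    y = cal.s_b + cal.k * cal.m_w * mass_weighted
    return KineticTrace(traj.times.copy(), y, background=cal.s_b, label=label)


def calibrate_from_monomer(
    signal_above_bg: float, conc: float, m_w: float = MW_AB40_KDA, s_b: float = 0.0
) -> ScatterCalibration:
    """Calibration from the signal of a pure monomer solution.

    E.g. 0.015 V above background at 1.5 mM implies 0.010 V at 1.0 mM by
    linearity.
    """
    if signal_above_bg <= 0 or conc <= 0:
        raise ValueError("signal and concentration must be > 0")
    return ScatterCalibration(s_b=s_b, k=signal_above_bg / (conc * m_w), m_w=m_w)


def calibrate_from_standards(points, m_w: float = MW_AB40_KDA) -> ScatterCalibration:
    """Least-squares calibration from standards of known ``c * M_w``.

    Parameters
    ----------
    points : sequence of (x, y)
        ``x`` is mass concentration times molecular weight (mM.kDa), ``y``
        the measured signal (V).  Slope gives ``k``, intercept ``S_b``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissae: all x equal")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("non-positive fitted slope; check standards")
    return ScatterCalibration(s_b=float(intercept), k=float(slope), m_w=m_w)


def n_ave_from_signal(trace: KineticTrace, monomer_signal_above_bg: float) -> np.ndarray:
    """Mass-weighted mean size series from a scattering trace.

    ``n_ave(t) = (y(t) - S_b) / monomer_signal_above_bg`` where the monomer
    reference is the signal above background of pure monomers at the same
    total concentration as the trace.
    """
    if trace.background is None:
        raise ValueError("trace has no background level")
    if monomer_signal_above_bg <= 0:
        raise ValueError("monomer reference signal must be > 0")
    return (trace.y - trace.background) / monomer_signal_above_bg


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere, ``pi d^3 / 6`` (nm -> nm^3)."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    return np.pi * diameter**3 / 6.0


def sphere_diameter(volume: float) -> float:
    """Diameter of a sphere of given volume (nm^3 -> nm)."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return (6.0 * volume / np.pi) ** (1.0 / 3.0)


def assembly_diameter(
    n: float, m_w: float = MW_AB40_KDA, density: float = DEFAULT_PROTEIN_DENSITY
) -> float:
    """Diameter (nm) of a spherical assembly of ``n`` molecules.

    Mass ``n * M_w`` at the given density (g/cm^3; 1.35 is typical for
    globular proteins) fixes the volume, hence the diameter.
    """
    if n <= 0 or m_w <= 0 or density <= 0:
        raise ValueError("n, M_w and density must be > 0")
    mass_g = n * m_w * _KDA_TO_G
    volume_cm3 = mass_g / density
    volume_nm3 = volume_cm3 * 1e21
    return sphere_diameter(volume_nm3)
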