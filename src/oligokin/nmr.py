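"""Quantitative comparison of 2D (13C-13C) spectra and shift-based
secondary-structure calls.

Spectra are intensity matrices over two ppm axes.  Pairwise comparison
follows the convention: symmetrize about the diagonal, normalize to the
total volume in a masked spectral region, compute the root-mean-squared
deviation over unmasked grid points, and scale the resulting heat map to a
maximum of 1.  The default aliphatic-aliphatic region excludes points
within 5 ppm of the diagonal and a 50-70 ppm square.

Crosspeak volumes are box integrals with uncertainties propagated from the
spectrum noise; chemical-shift classification flags residues whose CO/C-alpha
signals move upfield (or C-beta downfield) by more than 1.0 ppm relative to
a reference state, the empirical signature of beta-strand preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum2D",
    "RegionMask",
    "ShiftRecord",
    "ALIPHATIC_REGION",
    "CARBONYL_ALIPHATIC_REGION",
    "symmetrize",
    "normalize_region",
    "pairwise_rmsd",
    "crosspeak_volume",
    "volume_ratio",
    "classify_secondary_shift",
    "BETA_SHIFT_THRESHOLD_PPM",
]

#: Shift-difference magnitude (ppm) beyond which a change is called
#: beta-strand-indicative.
BETA_SHIFT_THRESHOLD_PPM = 1.0


@dataclass
class Spectrum2D:
    """2D intensity matrix with ppm axes and a noise estimate.

    ``intensity[i, j]`` corresponds to ``(axis1[i], axis2[j])``.  Axes are
    stored ascending internally; constructors accept descending axes and
    flip, recording the original order in ``meta``.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    intensity: np.ndarray
    noise_rms: float = 0.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.axis2 = np.asarray(self.axis2, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis1.size, self.axis2.size):
            raise ValueError("intensity shape does not match axes")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        for name, ax in (("axis1", self.axis1), ("axis2", self.axis2)):
            d = np.diff(ax)
            if np.all(d < 0):
                if name == "axis1":
                    self.axis1 = ax[::-1].copy()
                    self.intensity = self.intensity[::-1, :].copy()
                else:
                    self.axis2 = ax[::-1].copy()
                    self.intensity = self.intensity[:, ::-1].copy()
                self.meta.setdefault("flipped_axes", []).append(name)
            elif not np.all(d > 0):
                raise ValueError(f"{name} must be strictly monotone")

    @property
    def step(self) -> tuple[float, float]:
        return (
            float(np.mean(np.diff(self.axis1))),
            float(np.mean(np.diff(self.axis2))),
        )

    def point_area(self) -> float:
        """ppm^2 represented by one grid point."""
        s1, s2 = self.step
        return s1 * s2

    def scaled(self, factor: float) -> "Spectrum2D":
        return Spectrum2D(
            self.axis1.copy(),
            self.axis2.copy(),
            self.intensity * factor,
            noise_rms=self.noise_rms * abs(factor),
            label=self.label,
        )


@dataclass(frozen=True)
class RegionMask:
    """Spectral region selection with diagonal and box exclusions.

    ``bounds1``/``bounds2`` are (lo, hi) ppm windows per axis; grid points
    with ``|ppm1 - ppm2|`` below ``diagonal_exclusion_halfwidth`` or inside
    any square in ``square_exclusions`` are excluded.
    """

    bounds1: tuple[float, float]
    bounds2: tuple[float, float]
    diagonal_exclusion_halfwidth: float = 0.0
    square_exclusions: tuple = ()

    def __post_init__(self) -> None:
        for lo, hi in (self.bounds1, self.bounds2):
            if lo >= hi:
                raise ValueError("region bounds must be ordered (lo < hi)")
        if self.diagonal_exclusion_halfwidth < 0:
            raise ValueError("diagonal halfwidth must be >= 0")

    def select(self, spec: Spectrum2D) -> np.ndarray:
        """Boolean matrix of included grid points."""
        p1 = spec.axis1[:, None]
        p2 = spec.axis2[None, :]
        keep = (
            (p1 >= self.bounds1[0])
            & (p1 <= self.bounds1[1])
            & (p2 >= self.bounds2[0])
            & (p2 <= self.bounds2[1])
        )
        if self.diagonal_exclusion_halfwidth > 0:
            keep &= np.abs(p1 - p2) > self.diagonal_exclusion_halfwidth
        for (lo1, hi1), (lo2, hi2) in self.square_exclusions:
            keep &= ~((p1 >= lo1) & (p1 <= hi1) & (p2 >= lo2) & (p2 <= hi2))
        if not keep.any():
            raise ValueError("mask excludes the entire spectrum")
        return keep


#: Aliphatic-aliphatic comparison window: 10-75 ppm on both axes, excluding
#: points within 5 ppm of the diagonal and the 50-70 ppm square.
ALIPHATIC_REGION = RegionMask(
    bounds1=(10.0, 75.0),
    bounds2=(10.0, 75.0),
    diagonal_exclusion_halfwidth=5.0,
    square_exclusions=(((50.0, 70.0), (50.0, 70.0)),),
)

#: Carbonyl-aliphatic comparison window (no diagonal in this region).
CARBONYL_ALIPHATIC_REGION = RegionMask(bounds1=(165.0, 185.0), bounds2=(10.0, 75.0))


def _require_square(spec: Spectrum2D) -> None:
    if spec.axis1.size != spec.axis2.size or not np.allclose(spec.axis1, spec.axis2):
        raise ValueError("spectrum axes must match for symmetrization; resample first")


def symmetrize(spec: Spectrum2D) -> Spectrum2D:
    """Average the intensity matrix with its transpose (idempotent)."""
    _require_square(spec)
    sym = 0.5 * (spec.intensity + spec.intensity.T)
    return Spectrum2D(
        spec.axis1.copy(), spec.axis2.copy(), sym, noise_rms=spec.noise_rms, label=spec.label
    )


def normalize_region(spec: Spectrum2D, mask: RegionMask) -> Spectrum2D:
    """Divide intensities by the summed intensity over unmasked points."""
    keep = mask.select(spec)
    total = spec.intensity[keep].sum()
    if total <= 0:
        raise ValueError("non-positive total volume in the selected region")
    return Spectrum2D(
        spec.axis1.copy(),
        spec.axis2.copy(),
        spec.intensity / total,
        noise_rms=spec.noise_rms / total,
        label=spec.label,
    )


def resample_common_grid(specs: Sequence[Spectrum2D]) -> list[Spectrum2D]:
    """Bilinearly resample spectra onto the coarsest common square grid."""
    from scipy.interpolate import RegularGridInterpolator

    lo = max(max(s.axis1.min(), s.axis2.min()) for s in specs)
    hi = min(min(s.axis1.max(), s.axis2.max()) for s in specs)
    if lo >= hi:
        raise ValueError("spectra do not overlap in ppm")
    step = max(max(abs(s.step[0]), abs(s.step[1])) for s in specs)
    axis = np.arange(lo, hi + 0.5 * step, step)
    out = []
    for s in specs:
        interp = RegularGridInterpolator(
            (s.axis1, s.axis2), s.intensity, bounds_error=False, fill_value=0.0
        )
        g1, g2 = np.meshgrid(axis, axis, indexing="ij")
        vals = interp(np.stack([g1.ravel(), g2.ravel()], axis=-1)).reshape(axis.size, axis.size)
        out.append(Spectrum2D(axis, axis, vals, noise_rms=s.noise_rms, label=s.label))
    return out


def pairwise_rmsd(
    specs: Sequence[Spectrum2D],
    mask: RegionMask = ALIPHATIC_REGION,
    *,
    do_symmetrize: bool = True,
    blocks: dict[str, tuple[Sequence[int], Sequence[int]]] | None = None,
) -> dict:
    """Pairwise rmsd heat map of symmetrized, region-normalized spectra.

    Each pair's rmsd runs over the unmasked grid points; the full matrix is
    divided by its maximum entry, so the map is symmetric with zero
    diagonal and maximum exactly 1.  Optional ``blocks`` (label -> pair of
    index lists) are summarized as mean +/- standard deviation over the
    off-diagonal pairs they select.

    Returns a dict with ``matrix``, ``labels`` and ``block_summaries``.
    """
    if len(specs) < 2:
        raise ValueError("need at least two spectra")
    if not all(
        s.axis1.size == specs[0].axis1.size and np.allclose(s.axis1, specs[0].axis1)
        and np.allclose(s.axis2, specs[0].axis2)
        for s in specs
    ):
        specs = resample_common_grid(specs)
    prepped = []
    for s in specs:
        if do_symmetrize:
            s = symmetrize(s)
        prepped.append(normalize_region(s, mask))
    keep = mask.select(prepped[0])
    vecs = np.stack([s.intensity[keep] for s in prepped])
    k = len(prepped)
    rmsd = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rmsd[i, j] = rmsd[j, i] = np.sqrt(np.mean((vecs[i] - vecs[j]) ** 2))
    peak = rmsd.max()
    if peak > 0:
        rmsd = rmsd / peak
    summaries = {}
    if blocks:
        for name, (rows, cols) in blocks.items():
            vals = [rmsd[i, j] for i in rows for j in cols if i != j]
            vals = np.asarray(vals)
            summaries[name] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    return {
        "matrix": rmsd,
        "labels": [s.label for s in specs],
        "max_rmsd": float(peak),
        "block_summaries": summaries,
    }


def crosspeak_volume(
    spec: Spectrum2D, box: tuple[tuple[float, float], tuple[float, float]]
) -> tuple[float, float]:
    """Box-integrated crosspeak volume and its noise-derived uncertainty.

    Volume is the intensity sum over grid points in the box times the
    per-point ppm^2 area; the uncertainty is ``noise_rms * area *
    sqrt(n_points)`` (independent noise per point).
    """
    (lo1, hi1), (lo2, hi2) = box
    i = (spec.axis1 >= lo1) & (spec.axis1 <= hi1)
    j = (spec.axis2 >= lo2) & (spec.axis2 <= hi2)
    npts = int(i.sum()) * int(j.sum())
    if npts == 0:
        raise ValueError("box contains no grid points")
    area = spec.point_area()
    volume = float(spec.intensity[np.ix_(i, j)].sum() * area)
    unc = float(spec.noise_rms * area * np.sqrt(npts))
    return volume, unc


def volume_ratio(
    num: tuple[float, float], den: tuple[float, float]
) -> tuple[float, float]:
    """Ratio of two (volume, uncertainty) pairs with first-order
    independent-error propagation."""
    v1, s1 = num
    v2, s2 = den
    if v2 == 0:
        raise ValueError("denominator volume is zero")
    r = v1 / v2
    if v1 == 0:
        return r, abs(s1 / v2)
    return r, abs(r) * float(np.sqrt((s1 / v1) ** 2 + (s2 / v2) ** 2))


@dataclass(frozen=True)
class ShiftRecord:
    """One chemical-shift observation (DSS-referenced ppm)."""

    residue: str
    atom: str  # CO, CA, CB or CG
    shift: float  # ppm
    fwhm: float | None = None  # ppm
    state: str = ""  # monomer / oligomer / fibril / coil

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift <= 250.0:
            raise ValueError(f"shift {self.shift} ppm outside 0-250 ppm")


def classify_secondary_shift(
    reference: ShiftRecord, state: ShiftRecord, threshold: float = BETA_SHIFT_THRESHOLD_PPM
) -> str:
    """Call a shift change beta-indicative or not.

    CO and C-alpha: beta-indicative iff the state shift lies more than
    ``threshold`` ppm *upfield* (lower ppm) of the reference.  C-beta:
    beta-indicative iff more than ``threshold`` ppm *downfield*.  C-gamma
    carries no established secondary-shift signature: no call.
    """
    if reference.residue != state.residue or reference.atom != state.atom:
        raise ValueError("reference and state records must match residue and atom")
    atom = reference.atom.upper()
    delta = state.shift - reference.shift  # >0 downfield, <0 upfield
    if atom in ("CO", "C", "CA"):
        return "beta-indicative" if delta < -threshold else "not-indicative"
    if atom == "CB":
        return "beta-indicative" if delta > threshold else "not-indicative"
    if atom == "CG":
        return "no-call"
    raise ValueError(f"unknown atom type {reference.atom!r}")
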