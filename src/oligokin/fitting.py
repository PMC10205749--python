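"""Kinetic curve fitting and coagulation-model parameter estimation.

Three layers of analysis for stopped-flow kinetics of peptide
self-assembly:

1.  Empirical fits of scattering traces: a stretched exponential
    ``A1 + B1 (1 - exp[-(t/tau1)^beta1])`` for short times (t <= 0.5 s),
    and a composite form adding a second stretched exponential and a linear
    term for the full time range (the composite is fitted with the
    short-time parameters held fixed).
2.  Stretched-exponential fits of thioflavin-T fluorescence build-up
    curves, ``F(t) = F0 + A (1 - exp[-(t/tauF)^beta])``.
3.  Least-squares optimization of the coagulation-model parameters
    ``(r0, E0)`` at fixed threshold size ``Nth`` against a normalized
    scattering curve, and a scan of ``Nth`` to locate the best-fitting
    threshold.

The (r0, E0) optimization exploits an exact property of the coagulation
equations: all rates scale linearly with ``r0``, so the solution satisfies
``c_n(t; r0) = c_n(r0 t; 1)``.  One simulation at ``r0 = 1`` per ``E0``
therefore yields the fit deviation ``s^2`` for *every* candidate ``r0`` by
interpolation in scaled time, reducing the 2-D search to a deterministic
1-D profile optimization over ``E0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import coagulation as coag
from .scattering import KineticTrace, ScatterCalibration, calibrate_from_monomer

__all__ = [
    "StretchedExpParams",
    "CompositeParams",
    "ThTParams",
    "CoagFit",
    "CoagFitResult",
    "FitError",
    "eval_stretched",
    "fit_stretched",
    "eval_composite",
    "fit_composite",
    "eval_tht",
    "fit_tht",
    "fit_coagulation",
    "scan_nth",
    "fluorescence_per_molecule",
    "PAPER_SHORT_TIME_FIT",
    "PAPER_COMPOSITE_FIT",
    "default_fit_grid",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass(frozen=True)
class StretchedExpParams:
    """Parameters of ``S(t) - S_b = A1 + B1 (1 - exp[-(t/tau1)^beta1])``."""

    a1: float  # V, offset above background (the monomer signal at t = 0)
    b1: float  # V, amplitude
    tau1: float  # s
    beta1: float  # dimensionless, in (0, 1]
    stderr: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ValueError("B1 must be >= 0")
        if self.tau1 <= 0:
            raise ValueError("tau1 must be > 0")
        if not 0 < self.beta1 <= 1:
            raise ValueError("beta1 must be in (0, 1]")


@dataclass(frozen=True)
class CompositeParams:
    """Short-time stretched exponential plus a second stretched exponential
    and a linear term; the ``base`` block is held fixed during fitting."""

    base: StretchedExpParams
    a2: float  # V/s, linear slope
    b2: float  # V, second amplitude
    tau2: float  # s
    beta2: float  # dimensionless, in (0, 1]
    stderr: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.b2 < 0:
            raise ValueError("B2 must be >= 0")
        if self.tau2 <= 0:
            raise ValueError("tau2 must be > 0")
        if not 0 < self.beta2 <= 1:
            raise ValueError("beta2 must be in (0, 1]")


@dataclass(frozen=True)
class ThTParams:
    """Parameters of ``F(t) = F0 + A (1 - exp[-(t/tauF)^beta])``."""

    f0: float  # a.u., unbound-dye fluorescence
    a: float  # a.u., amplitude
    tau_f: float  # s
    beta: float  # dimensionless, in (0, 1]
    stderr: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("A must be >= 0")
        if self.tau_f <= 0:
            raise ValueError("tauF must be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


#: Short-time (t <= 0.5 s) stretched-exponential fit of the 1.5 mM
#: scattering data, with A1 pinned to the measured monomer level.
PAPER_SHORT_TIME_FIT = StretchedExpParams(a1=0.015, b1=0.1147, tau1=0.141, beta1=0.540)

#: Full-range composite fit of the 1.5 mM scattering data (base fixed).
PAPER_COMPOSITE_FIT = CompositeParams(
    base=PAPER_SHORT_TIME_FIT, a2=0.00036057, b2=0.43465, tau2=176.0, beta2=0.6127
)


def _stretched(t, tau, beta):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = 1.0 - np.exp(-((t[pos] / tau) ** beta))
    return out


def eval_stretched(params: StretchedExpParams, t) -> np.ndarray:
    """Signal above background (V) of the stretched-exponential form."""
    return params.a1 + params.b1 * _stretched(t, params.tau1, params.beta1)


def eval_composite(params: CompositeParams, t) -> np.ndarray:
    """Signal above background (V) of the composite empirical form."""
    t = np.asarray(t, dtype=float)
    b = params.base
    return (
        b.a1
        + params.a2 * t
        + b.b1 * _stretched(t, b.tau1, b.beta1)
        + params.b2 * _stretched(t, params.tau2, params.beta2)
    )


def eval_tht(params: ThTParams, t) -> np.ndarray:
    """Fluorescence (a.u.) of the ThT stretched-exponential form."""
    return params.f0 + params.a * _stretched(t, params.tau_f, params.beta)


def _positive_time_data(trace: KineticTrace, t_max: float | None):
    # the stretched exponential is non-smooth at t = 0 for beta < 1
    mask = trace.t > 0
    if t_max is not None:
        mask &= trace.t <= t_max
    t, y = trace.t[mask], trace.y[mask]
    if t.size < 10:
        raise FitError("need at least 10 points with t > 0")
    if t.max() / t.min() < 10:
        warnings.warn("time points span less than one decade", stacklevel=3)
    return t, y


def _run_fit(model, y, params, t) -> lmfit.model.ModelResult:
    result = model.fit(y, params, t=t)
    if not result.success:
        raise FitError(f"fit did not converge: {result.message}")
    return result


def _stderr_dict(result) -> dict:
    return {
        name: (par.stderr if par.stderr is not None else np.nan)
        for name, par in result.params.items()
        if par.vary
    }


def fit_stretched(
    trace: KineticTrace, fixed_a1: float | None = None, t_max: float | None = None
) -> StretchedExpParams:
    """Nonlinear least-squares stretched-exponential fit of a trace.

    ``trace.y`` must already be background-subtracted (signal above ``S_b``).
    ``A1`` may be pinned to a measured monomer signal.  Standard errors from
    the local curvature are reported in ``stderr``.
    """
    t, y = _positive_time_data(trace, t_max)

    def func(t, a1, b1, tau1, beta1):
        return a1 + b1 * _stretched(t, tau1, beta1)

    model = lmfit.Model(func)
    span = max(y.max() - y.min(), 1e-12)
    params = model.make_params(
        a1={"value": fixed_a1 if fixed_a1 is not None else y.min(), "vary": fixed_a1 is None},
        b1={"value": span, "min": 0},
        tau1={"value": np.median(t), "min": 1e-12},
        beta1={"value": 0.7, "min": 1e-3, "max": 1.0},
    )
    result = _run_fit(model, y, params, t)
    v = result.params
    return StretchedExpParams(
        a1=v["a1"].value,
        b1=v["b1"].value,
        tau1=v["tau1"].value,
        beta1=v["beta1"].value,
        stderr=_stderr_dict(result),
    )


def fit_composite(trace: KineticTrace, base: StretchedExpParams) -> CompositeParams:
    """Fit the composite form with the short-time block held fixed.

    Only ``(A2, B2, tau2, beta2)`` vary; ``base`` must come from a prior
    short-time fit.
    """
    t, y = _positive_time_data(trace, None)
    resid = y - eval_stretched(base, t)

    def func(t, a2, b2, tau2, beta2):
        return a2 * t + b2 * _stretched(t, tau2, beta2)

    model = lmfit.Model(func)
    span = max(resid.max(), 1e-12)
    params = model.make_params(
        a2={"value": max(resid[-1] / t[-1] * 0.5, 0.0)},
        b2={"value": span, "min": 0},
        tau2={"value": np.median(t), "min": 1e-12},
        beta2={"value": 0.7, "min": 1e-3, "max": 1.0},
    )
    result = _run_fit(model, resid, params, t)
    v = result.params
    return CompositeParams(
        base=base,
        a2=v["a2"].value,
        b2=v["b2"].value,
        tau2=v["tau2"].value,
        beta2=v["beta2"].value,
        stderr=_stderr_dict(result),
    )


def fit_tht(trace: KineticTrace, fixed_f0: float | None = 0.23) -> ThTParams:
    """Stretched-exponential fit of a ThT fluorescence build-up curve.

    ``F0`` (unbound-dye fluorescence) is pinned by default; pass
    ``fixed_f0=None`` to fit it.
    """
    t, y = _positive_time_data(trace, None)

    def func(t, f0, a, tau_f, beta):
        return f0 + a * _stretched(t, tau_f, beta)

    model = lmfit.Model(func)
    span = max(y.max() - y.min(), 1e-12)
    params = model.make_params(
        f0={"value": fixed_f0 if fixed_f0 is not None else y.min(), "vary": fixed_f0 is None},
        a={"value": span, "min": 0},
        tau_f={"value": np.median(t), "min": 1e-12},
        beta={"value": 0.7, "min": 1e-3, "max": 1.0},
    )
    result = _run_fit(model, y, params, t)
    v = result.params
    return ThTParams(
        f0=v["f0"].value,
        a=v["a"].value,
        tau_f=v["tau_f"].value,
        beta=v["beta"].value,
        stderr=_stderr_dict(result),
    )


# ---------------------------------------------------------------------------
# Coagulation-model parameter estimation


@dataclass
class CoagFit:
    """Optimized coagulation parameters at one fixed threshold size."""

    nth: float
    r0: float  # mM^-1 s^-1
    e0: float
    s2: float  # squared deviation of normalized curves over the fit grid
    n_simulations: int = 0
    boundary_flags: list = field(default_factory=list)
    overflow_limited: bool = False


@dataclass
class CoagFitResult:
    """Result of a threshold-size scan: per-Nth optima and the argmin."""

    per_nth: pd.DataFrame  # columns nth, r0, e0, s2
    best_nth: float
    target: object = None

    @property
    def best(self) -> CoagFit:
        row = self.per_nth.loc[self.per_nth["s2"].idxmin()]
        return CoagFit(nth=row["nth"], r0=row["r0"], e0=row["e0"], s2=row["s2"])


def default_fit_grid(n_points: int = 200) -> np.ndarray:
    """Log-spaced fit times from 1 ms to 3600 s (uniform weight per point).

    Log spacing spreads the five decades of observed kinetics evenly and
    prevents the long-time linear regime from dominating the deviation.
    """
    return np.logspace(-3, np.log10(3600.0), n_points)


def _normalized_target(target, grid: np.ndarray, cal: ScatterCalibration) -> np.ndarray:
    """Target curve in units of the 1.0 mM monomer signal above background."""
    ref_1mm = cal.monomer_signal(1.0)
    if isinstance(target, CompositeParams):
        return eval_composite(target, grid) / ref_1mm
    if isinstance(target, StretchedExpParams):
        return eval_stretched(target, grid) / ref_1mm
    if isinstance(target, KineticTrace):
        y = target.y - (target.background or 0.0)
        pos = target.t > 0
        if pos.sum() < 2:
            raise ValueError("target trace needs at least two t > 0 points")
        return np.interp(np.log(grid), np.log(target.t[pos]), y[pos]) / ref_1mm
    raise TypeError(f"unsupported target type {type(target)!r}")


class _ScaledCurve:
    """n_ave as a function of scaled time theta = r0 * t at r0 = 1."""

    def __init__(
        self,
        e0: float,
        nth: float,
        c0: float,
        nmax: int,
        theta_min: float,
        theta_max: float,
        rtol: float,
    ):
        n_theta = max(int(40 * np.log10(theta_max / theta_min)), 50)
        theta = np.logspace(np.log10(theta_min), np.log10(theta_max), n_theta)
        init = coag.monomer_distribution(c0, nmax)
        params = coag.KernelParams(r0=1.0, e0=e0, nth=nth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", coag.OverflowWarning)
            traj = coag.simulate_coagulation(
                init, params, theta, rtol=rtol, stop_overflow_frac=2e-3
            )
        self.truncated = traj.meta.get("terminated_early", False)
        self.log_theta = np.log(traj.times)
        self.n_ave = traj.n_ave_series()

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        # flat extension: below the simulated range n_ave ~ 1, above it the
        # last value (heavily penalized by s^2, which is the intent)
        return np.interp(np.log(theta), self.log_theta, self.n_ave, left=1.0)


def fit_coagulation(
    target,
    nth: float,
    c0: float = 1.5,
    cal: ScatterCalibration | None = None,
    grid: np.ndarray | None = None,
    *,
    nmax: int = coag.DEFAULT_NMAX,
    r0_bounds: tuple[float, float] = (1e-4, 0.05),
    e0_bounds: tuple[float, float] = (1.0 + 1e-2, 1.0 + 1e4),
    fix_e0: float | None = None,
    rtol: float = coag.DEFAULT_RTOL,
    coarse_points: int = 13,
) -> CoagFit:
    """Optimize ``(r0, E0)`` at fixed ``Nth`` against a normalized target.

    Both the simulated signal and the target are normalized to the signal
    from a 1.0 mM monomer solution (for the simulation that normalized
    signal is simply ``c0 * n_ave(t)`` in mM), and the deviation

        s^2 = sum_grid [sim_norm(t) - target_norm(t)]^2

    is minimized over a log-spaced time grid with uniform weight per point.

    The search is deterministic: because ``r0`` only rescales time, one
    simulation at ``r0 = 1`` per candidate ``E0`` gives ``s^2(r0)`` for all
    ``r0`` by interpolation; the ``E0`` profile is minimized by a coarse
    logarithmic grid in ``E0 - 1`` followed by bounded scalar refinement.

    Parameters
    ----------
    target : CompositeParams, StretchedExpParams or KineticTrace
        Empirical curve (V above background) to fit.
    fix_e0 : float, optional
        Lock the enhancement factor (e.g. ``1.0`` for the bare kernel) and
        optimize ``r0`` only.
    """
    if cal is None:
        cal = calibrate_from_monomer(0.015, 1.5)
    if grid is None:
        grid = default_fit_grid()
    grid = np.asarray(grid, dtype=float)
    target_norm = _normalized_target(target, grid, cal)

    log_r0 = np.log(np.asarray(r0_bounds))
    theta_min = r0_bounds[0] * grid[0]
    theta_max = r0_bounds[1] * grid[-1]

    n_sims = 0
    curves: dict[float, _ScaledCurve] = {}

    def curve_for(e0: float) -> _ScaledCurve:
        nonlocal n_sims
        key = round(float(e0), 10)
        if key not in curves:
            curves[key] = _ScaledCurve(e0, nth, c0, nmax, theta_min, theta_max, rtol)
            n_sims += 1
        return curves[key]

    def s2_of_r0(curve: _ScaledCurve, r0: float) -> float:
        sim_norm = c0 * curve(r0 * grid)
        return float(np.sum((sim_norm - target_norm) ** 2))

    def best_r0(curve: _ScaledCurve) -> tuple[float, float]:
        # dense log scan then local parabolic refinement (interpolation only)
        r0s = np.exp(np.linspace(log_r0[0], log_r0[1], 240))
        vals = np.array([s2_of_r0(curve, r) for r in r0s])
        i = int(np.argmin(vals))
        lo = np.log(r0s[max(i - 1, 0)])
        hi = np.log(r0s[min(i + 1, r0s.size - 1)])
        if hi <= lo:
            return float(r0s[i]), float(vals[i])
        res = minimize_scalar(
            lambda lr: s2_of_r0(curve, np.exp(lr)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if res.fun <= vals[i]:
            return float(np.exp(res.x)), float(res.fun)
        return float(r0s[i]), float(vals[i])

    def profile(e0: float) -> tuple[float, float]:
        return best_r0(curve_for(e0))

    flags: list[str] = []
    if fix_e0 is not None:
        e0_opt = float(fix_e0)
        r0_opt, s2_opt = profile(e0_opt)
    else:
        # coarse profile over log(E0 - 1)
        log_u = np.linspace(np.log(e0_bounds[0] - 1.0), np.log(e0_bounds[1] - 1.0), coarse_points)
        prof = [profile(1.0 + np.exp(lu)) for lu in log_u]
        s2s = np.array([p[1] for p in prof])
        i = int(np.argmin(s2s))
        lo = log_u[max(i - 1, 0)]
        hi = log_u[min(i + 1, log_u.size - 1)]
        res = minimize_scalar(
            lambda lu: profile(1.0 + np.exp(lu))[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 0.02},
        )
        if res.fun <= s2s[i]:
            lu_opt = float(res.x)
        else:
            lu_opt = float(log_u[i])
        e0_opt = 1.0 + np.exp(lu_opt)
        r0_opt, s2_opt = profile(e0_opt)
        if i in (0, log_u.size - 1):
            flags.append("E0 at search boundary")

    if not (r0_bounds[0] * 1.05 < r0_opt < r0_bounds[1] / 1.05):
        flags.append("r0 near search boundary")
    if flags:
        warnings.warn("; ".join(flags) + f" (Nth={nth})", stacklevel=2)

    return CoagFit(
        nth=nth,
        r0=r0_opt,
        e0=e0_opt,
        s2=s2_opt,
        n_simulations=n_sims,
        boundary_flags=flags,
        overflow_limited=any(c.truncated for c in curves.values()),
    )


def scan_nth(
    target,
    nth_grid,
    c0: float = 1.5,
    cal: ScatterCalibration | None = None,
    grid: np.ndarray | None = None,
    **kwargs,
) -> CoagFitResult:
    """Re-optimize ``(r0, E0)`` at each threshold size and locate the
    ``Nth`` with minimal fit deviation ``s^2``."""
    nth_grid = np.asarray(nth_grid, dtype=float)
    if nth_grid.size < 1:
        raise ValueError("nth_grid must be non-empty")
    rows = []
    for nth in nth_grid:
        fit = fit_coagulation(target, nth, c0=c0, cal=cal, grid=grid, **kwargs)
        rows.append({"nth": nth, "r0": fit.r0, "e0": fit.e0, "s2": fit.s2})
    table = pd.DataFrame(rows)
    best_nth = float(table.loc[table["s2"].idxmin(), "nth"])
    return CoagFitResult(per_nth=table, best_nth=best_nth, target=target)


def fluorescence_per_molecule(
    tht: KineticTrace,
    n_ave_trace: KineticTrace | None = None,
    *,
    n_ave_times: np.ndarray | None = None,
    n_ave_values: np.ndarray | None = None,
    c0: float = 1.5,
    f0: float = 0.23,
    n_points: int = 100,
) -> pd.DataFrame:
    """Pair background-subtracted fluorescence per molecule with the
    contemporaneous mass-weighted mean size.

    The total number of molecules is constant, so "per molecule" divides
    ``F(t) - F0`` by the total peptide concentration ``c0``; pairing the
    result with ``n_ave(t)`` from scattering reveals at what mean size the
    per-molecule fluorescence saturates.  Purely descriptive: no threshold
    is detected.

    Provide the size series either as a ``KineticTrace`` (``y`` holding
    ``n_ave``) or as explicit ``n_ave_times`` / ``n_ave_values`` arrays.
    """
    if n_ave_trace is not None:
        n_ave_times, n_ave_values = n_ave_trace.t, n_ave_trace.y
    if n_ave_times is None or n_ave_values is None:
        raise ValueError("need an n_ave series")
    n_ave_times = np.asarray(n_ave_times, dtype=float)
    n_ave_values = np.asarray(n_ave_values, dtype=float)

    t_lo = max(tht.t.min(), n_ave_times.min())
    t_hi = min(tht.t.max(), n_ave_times.max())
    if t_lo >= t_hi:
        raise ValueError("fluorescence and size series have disjoint time ranges")
    t_common = np.linspace(t_lo, t_hi, n_points)
    f = np.interp(t_common, tht.t, tht.y) - f0
    nave = np.interp(t_common, n_ave_times, n_ave_values)
    return pd.DataFrame(
        {"t": t_common, "n_ave": nave, "f_per_molecule": f / c0}
    )
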