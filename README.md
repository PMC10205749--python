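# oligokin

Quantitative analysis of the earliest stages of amyloid-β (Aβ40)
self-assembly, for researchers combining time-resolved light scattering
with low-temperature ssNMR of freeze-trapped intermediates.  The package
implements:

* a **mass-conserving coagulation model** of oligomer growth — clusters of
  sizes *n*, *m* fuse irreversibly at rates
  r(n,m) = E(n,m)·(2 + (m/n)^⅓ + (n/m)^⅓)·r₀ with a small-oligomer
  enhancement E(n,m) = 1 + (E₀−1)·exp[−(n²+m²)/N_th²] — integrated with an
  O(N log N) separable-kernel right-hand side and cross-checked by an
  event-driven stochastic simulation;
* a **light-scattering forward model** S(t) = S_b + k·M_w·Σ c_n(t)·n,
  calibration helpers, and extraction of the mass-weighted mean oligomer
  size n_ave(t) = Σ n·c_n / Σ c_n from signal traces;
* **stretched-exponential kinetic fitting** — short-time
  A₁ + B₁(1 − exp[−(t/τ₁)^β₁]) fits, composite long-time fits, and ThT
  fluorescence fits — plus least-squares optimization of (r₀, E₀) at fixed
  N_th against normalized scattering curves and an N_th scan;
* **2D ssNMR spectrum comparison**: symmetrized, region-normalized
  pairwise rmsd heat maps with diagonal/box exclusions, crosspeak volumes
  with noise-propagated uncertainties, and β-strand calls from
  chemical-shift changes (CO/Cα upfield or Cβ downfield by > 1.0 ppm);
* **seeded synthetic-data generators** for stopped-flow traces (0.25 ms
  sampling, replicate-averaged Gaussian noise) and Gaussian-crosspeak 2D
  spectra, so the full pipeline is testable without measured data.

See `docs/methods.md` for the model, conventions (including the same-size
fusion event-rate convention) and numerical choices.

## Worked example

Fit the coagulation model to the empirical composite curve describing the
1.5 mM scattering data, at a fixed enhancement threshold of 16:

```python
from oligokin.fitting import PAPER_COMPOSITE_FIT, fit_coagulation

fit = fit_coagulation(PAPER_COMPOSITE_FIT, nth=16.0)
print(f"r0 = {fit.r0:.4g} mM^-1 s^-1, E0 = {fit.e0:.1f}, s2 = {fit.s2:.0f}")
```

prints

```
r0 = 0.004265 mM^-1 s^-1, E0 = 98.8, s2 = 4299
```

i.e. large-oligomer fusion proceeds at ~4·10⁻³ mM⁻¹s⁻¹ — eight orders of
magnitude below the diffusion limit of ~8·10⁵ mM⁻¹s⁻¹ returned by
`diffusion_limited_r0(PhysicalConditions(297, 2.0))` — while oligomers
smaller than ~16 molecules fuse ~100× faster.  Simulating at the fitted
parameters and pushing the trajectory through the scattering forward
model:

```python
import numpy as np
from oligokin import (KernelParams, monomer_distribution,
                      simulate_coagulation, calibrate_from_monomer,
                      forward_signal, n_ave_from_signal)

params = KernelParams(r0=fit.r0, e0=fit.e0, nth=16.0)
traj = simulate_coagulation(monomer_distribution(1.5, 2048),
                            params, np.logspace(-3, np.log10(3600), 200))
cal = calibrate_from_monomer(0.015, 1.5)   # 0.015 V above background at 1.5 mM
trace = forward_signal(traj, cal)
nave = n_ave_from_signal(trace, cal.monomer_signal(1.5))
print(f"n_ave at 0.5 s: {np.interp(0.5, traj.times, nave):.1f}, "
      f"at 600 s: {np.interp(600, traj.times, nave):.0f}")
```

```
n_ave at 0.5 s: 2.7, at 600 s: 47
```

— oligomers of a few molecules form within the first second, growing to
~50-mers by ten minutes, with the signal rising nearly linearly at long
times.  The same stages are scriptable from the shell via the `oligokin`
CLI (`simulate`, `forward`, `fit stretched|composite|coag|tht`,
`scan-nth`, `spectra rmsd|volume|classify`, `synth`, `run`).

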