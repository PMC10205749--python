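# Methods

## The coagulation model

`oligokin.coagulation` integrates an irreversible coagulation
(Smoluchowski) scheme for peptide oligomers: clusters of sizes *n* and *m*
fuse to size *n + m* with rate constants

    r(n, m) = E(n, m) · (2 + (m/n)^⅓ + (n/m)^⅓) · r₀,
    E(n, m) = 1 + (E₀ − 1) · exp[−(n² + m²)/N_th²].

The geometric factor is the size dependence of diffusion-limited encounter
of spheres whose radii scale as *n*^⅓ (Stokes–Einstein); *r₀* (mM⁻¹ s⁻¹)
sets the absolute scale, and *E(n, m)* multiplies rates by ≈ *E₀* while
√(n² + m²) ≲ *N_th*, encoding faster fusion of small oligomers.  The model
has no fragmentation, dissociation, or fibril nucleation/elongation terms,
and no spatial or shear dependence: it describes the pre-fibrillar growth
regime only.

The state is the vector of monomer-equivalent mass concentrations *c_n*
(mM), so Σ *c_n* is the total peptide concentration and number
concentrations entering rate products are *c_m / m*.  The evolution
equations carry a (1 + δ_{n,m}) factor on the loss sum and gain sums that
run to *n*/2 (even *n*) or (*n* − 1)/2 (odd *n*) **without** halving the
*m* = *n*/2 term: same-size fusion events fire at rate K·ν², twice the
standard Smoluchowski self-pair convention.  The stochastic oracle and the
closed-form helpers adopt the same convention (the constant-kernel rate
estimator exposes both conventions, which differ by exactly a factor of 2,
because order-of-magnitude estimates of the monomer fusion rate depend on
which is assumed).

### Numerics

* **Truncation.**  Default N_max = 2048, adequate for the 1.5 mM / 3600 s
  regime (overflow fraction ~5·10⁻¹¹ at the best-fit parameters).  Fusions
  producing sizes > N_max deposit their mass into an inert overflow bin;
  a warning is recorded when the overflow exceeds 10⁻³ of the total.
* **Conservation.**  The overflow derivative is defined as minus the sum
  of all other mass derivatives, making total mass a *linear invariant* of
  the right-hand side; Runge–Kutta methods preserve linear invariants
  exactly, so conservation holds to rounding error independent of solver
  tolerance.
* **Fast right-hand side.**  Every kernel factor is separable in (n, m)
  — cube-root powers and exp(−n²/N_th²)·exp(−m²/N_th²) — so the loss sums
  are six inner products and the gain term is four FFT convolutions:
  O(N log N) per evaluation.  A direct O(N²) implementation from the dense
  kernel matrix is kept as a reference (they agree to ~10⁻¹⁵ relative at
  N = 64) and is used for simulations with overridden kernels.
* **Integrator.**  `scipy.integrate.solve_ivp` with DOP853, rtol 10⁻⁶,
  atol 10⁻¹² mM.  The fast enhanced-rate modes decay as monomers deplete,
  so an explicit high-order method with adaptive steps handles the ~5
  orders of magnitude between enhanced and bare rates without a stiff
  solver (whose dense Jacobian would be prohibitive at N = 2048).
* **Degenerate inputs.**  r₀ = 0 (or an all-zero state) is legal and
  returns the initial state; concentrations more negative than a small
  tolerance raise an integration error rather than being silently clipped.

### Stochastic oracle

A finite-system event-driven (Marcus–Lushnikov/Gillespie) simulation with
the same self-pair convention: the propensity of size pair (n, n) is
K·N_n(N_n − 1)/V, not half that.  Total event rates are computed exactly
per step via the separable kernel sums; the firing pair is drawn from the
explicit propensity matrix over active sizes.  It serves purely as an
independent check of the deterministic integrator (ensemble mean of the
mass-weighted mean size agrees within Monte-Carlo error); it is not the
production path.

## Scattering forward model

The 90° scattering voltage is S(t) = S_b + k·M_w·Σ c_n(t)·n, so
S − S_b ∝ mass-weighted mean size n_ave.  Refractive-index-increment
variation with size, the second virial coefficient, and form factors are
deliberately ignored — appropriate for globular particles far below the
illumination wavelength when only approximate n_ave is extracted, and a
stated limitation otherwise.  Calibration comes either from a single
monomer solution of known concentration (0.015 V above background at
1.5 mM ⇒ 0.010 V at 1.0 mM by linearity) or from a straight-line fit to
protein standards of known c·M_w.  The overflow bin scatters with size
N_max, a conservative underestimate that is flagged whenever the overflow
is non-negligible.  The geometry helpers assume spherical assemblies with
density 1.35 g/cm³ (typical globular protein; the density is this
package's documented assumption, giving ~9 nm for a 70-mer).

## Empirical kinetic fits

Stretched exponentials A₁ + B₁(1 − exp[−(t/τ₁)^β₁]) are fitted by bounded
nonlinear least squares (lmfit, β ∈ (0, 1], τ > 0, B ≥ 0), with parameter
standard errors from the local curvature.  Fits use t > 0 points only (the
form is non-smooth at 0 for β < 1).  A₁ is pinned to the measured monomer
level by default, since the offset and amplitude are otherwise strongly
correlated on plateauing data.  The composite long-time form adds A₂·t +
B₂(1 − exp[−(t/τ₂)^β₂]) with the short-time block held fixed — fitting the
residual keeps the two time scales from trading against each other.  ThT
fluorescence uses the same machinery with F₀ pinned to the unbound-dye
level (0.23) by default.  `fluorescence_per_molecule` only interpolates
the two observables onto a common grid and divides by total concentration;
it detects no threshold.

## (r₀, E₀) optimization and the N_th scan

The target curve (either a measured trace or the composite-fit
reconstruction) and the simulated signal are both normalized to the
1.0 mM monomer signal; for the simulation that normalized signal is simply
c₀·n_ave(t)/1 mM.  The deviation is

    s² = Σ over 200 log-spaced times in [10⁻³, 3.6·10³] s
         of [sim_norm(t) − target_norm(t)]².

Log spacing with uniform weights spreads the five observed decades evenly;
with linear spacing the long-time linear regime would dominate.  The grid,
weighting and optimizer are this package's choices — the recovered
(r₀, E₀) can move at the tens-of-percent level under other defensible
choices, which is why agreement with external estimates should be judged
at the factor-of-two level.

The search itself exploits an exact rescaling property: all rates are
proportional to r₀, so c_n(t; r₀) = c_n(r₀·t; 1).  One simulation at
r₀ = 1 per candidate E₀ (on a dense logarithmic scaled-time grid) gives
s²(r₀) for every r₀ by interpolation, collapsing the 2-D search to a 1-D
profile over E₀.  That profile is minimized by a coarse logarithmic grid
in E₀ − 1 (13 points spanning 10⁻² to 10⁴) followed by bounded scalar
refinement; the inner r₀ minimization is a dense log-scan plus bracketed
refinement on the interpolant.  The procedure is derivative-free,
deterministic, and needs ~20–30 ODE solutions per N_th instead of
hundreds.  Scaled-time simulations stop early (via an integration event)
once the overflow bin passes 2·10⁻³ of the mass; beyond that point the
curve is extended flat, which penalizes the corresponding (very large) r₀
values — exactly the intended behavior, since such fits already overshoot
the target grossly.  Optima within ~5% of a search boundary are flagged
(at small N_th the optimal E₀ genuinely runs away to the upper bound, and
the flag fires).

No uncertainties are claimed for (r₀, E₀): the target reconstruction and
the discretionary s² definition dominate any curvature-based error bar.

## 2D spectrum comparison

Spectra are plain intensity matrices over two ppm axes (stored ascending;
descending inputs are flipped and noted).  Pairwise comparison:
symmetrize about the diagonal (average with the transpose), normalize to
the total intensity inside the selected region, take the rms difference
over unmasked grid points, and divide the resulting matrix by its maximum.
The rmsd therefore runs over grid points, not picked crosspeaks.  Default
regions: aliphatic–aliphatic 10–75 × 10–75 ppm excluding |Δppm| ≤ 5 about
the diagonal and the 50–70 ppm square; carbonyl–aliphatic
165–185 × 10–75 ppm.  The numeric bounds are this package's defaults (the
qualitative regions are standard; exact window edges are configurable).
Crosspeak volumes are box sums times the per-point ppm² area with
uncertainty noise_rms·area·√N_points; ratios use first-order
independent-error propagation.  Apodization and other spectral processing
are out of scope — the module consumes processed matrices, and synthetic
spectra are generated already "processed".

Secondary-structure calls use the empirical secondary-shift signature:
relative to a reference state (monomer or random coil), CO or Cα shifts
more than 1.0 ppm *upfield*, or Cβ shifts more than 1.0 ppm *downfield*,
indicate β-strand preference; Cγ gives no call.  Applied to the bundled
monomer→oligomer shift table this flags V18, F19, V24, A30, I31, G33 and
M35 from CO/Cα and V18, F19, A30, I31, L34 from Cβ.

## Synthetic data

Generators are pure functions of (parameters, seed) built on
`numpy.random.default_rng`.  Traces emulate stopped-flow photomultiplier
acquisition: 0.25 ms sampling, additive Gaussian noise on a constant
background, with R-replicate averaging reducing the noise by √R.  Default
noise σ = 0.002 V with 6 averaged replicates makes the short-time
parameter-recovery tests meaningful at the published parameter values; the
true instrument noise is not published, so σ is a modeling choice, not an
instrument spec.  Spectra are sums of 2D Gaussians with FWHM linewidths on
the 2–7 ppm scale of the tabulated frozen-solution data, plus seeded
noise whose rms is recorded truthfully.  The generators do not emulate
raw 12.5 µs PMT samples, photon statistics, heteroscedastic noise,
baseline drift, or spectrometer artifacts — so passing recovery tests show
correctness of the estimators under the stated noise model, not robustness
to every instrumental pathology of real data.

## Problem sizes used in tests and the acceptance script

Simulations use N_max = 2048 for fitting-quality runs and 128–512 for
property tests; the stochastic cross-checks use 10⁴ particles and 20 seeds
(2000 particles for the capped dimerization case).  The N_th scan covers
{2, 4, 8, 16, 32, 64} with the 200-point fit grid.  These sizes reproduce
the published regime directly; nothing is scaled down.

## Known limitations

* The coagulation fit is conditioned on the empirical composite
  reconstruction of the data, not on raw traces; with the published
  parameters for the 0.75 mM dataset unavailable, only the 1.5 mM regime
  is exercised end to end.
* The spheroid aspect-ratio scattering correction is not implemented (the
  underlying optical model is under-specified); the forward model is
  shape-blind.
* rmsd block values from the real spectra require the deposited
  experimental data; the package reproduces the statistics' properties on
  synthetic spectra only.
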