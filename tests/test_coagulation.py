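"""Kernel algebra, ODE integration, conservation laws and the stochastic
cross-check of the coagulation model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligokin.coagulation import (
    IntegrationError,
    KernelParams,
    MassDistribution,
    PhysicalConditions,
    constant_kernel_rate_estimate,
    diffusion_limited_r0,
    enhancement,
    fusion_rate,
    kernel_matrix,
    monomer_distribution,
    n_ave,
    simulate_coagulation,
    stochastic_oracle,
)
from oligokin.coagulation import _DirectRHS, _SeparableRHS

sizes_st = st.integers(min_value=1, max_value=5000)
params_st = st.builds(
    KernelParams,
    r0=st.floats(1e-4, 10.0),
    e0=st.floats(1.0, 500.0),
    nth=st.floats(1.0, 100.0),
)


class TestKernel:
    @pytest.mark.parametrize(
        "n, m, params, expected",
        [
            (1, 1, KernelParams(r0=1, e0=1, nth=16), 1.0),
            (1, 1, KernelParams(r0=1, e0=120, nth=16), 1 + 119 * np.exp(-2 / 256)),
            (5000, 5000, KernelParams(r0=1, e0=120, nth=16), 1.0),
        ],
    )
    def test_enhancement_values(self, n, m, params, expected):
        assert enhancement(n, m, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "n, m, params, expected",
        [
            (1, 1, KernelParams(r0=1.0), 4.0),
            (7, 7, KernelParams(r0=1.0), 4.0),
            (8, 1, KernelParams(r0=1.0), 4.5),
            (1, 8, KernelParams(r0=1.0), 4.5),
            # composition of geometric factor and enhancement at the
            # published best-fit point
            (
                1,
                1,
                KernelParams(r0=0.0054, e0=120, nth=16),
                4 * 0.0054 * (1 + 119 * np.exp(-2 / 256)),
            ),
        ],
    )
    def test_fusion_rate_values(self, n, m, params, expected):
        assert fusion_rate(n, m, params) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=sizes_st, m=sizes_st, params=params_st)
    def test_symmetry_and_bounds(self, n, m, params):
        assert fusion_rate(n, m, params) == fusion_rate(m, n, params)
        e = enhancement(n, m, params)
        assert 1.0 <= e <= params.e0 or params.e0 == 1.0
        # geometric factor minimum is 4 at n = m
        assert fusion_rate(n, m, params) >= 4.0 * params.r0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=sizes_st, m=sizes_st, nth=st.floats(1.0, 100.0), r0=st.floats(1e-4, 10.0))
    def test_e0_one_reduces_to_bare_kernel_bitwise(self, n, m, nth, r0):
        enhanced = fusion_rate(n, m, KernelParams(r0=r0, e0=1.0, nth=nth))
        bare = (2 + (np.cbrt(m) / np.cbrt(n) + np.cbrt(n) / np.cbrt(m))) * r0
        assert enhanced == bare

    def test_rejects_nonpositive_sizes(self):
        with pytest.raises(ValueError):
            enhancement(0, 1, KernelParams(r0=1))
        with pytest.raises(ValueError):
            fusion_rate(1, -2, KernelParams(r0=1))


class TestNAve:
    def test_pure_monomer_is_one(self):
        assert n_ave(monomer_distribution(1.5, 64)) == 1.0

    def test_monomer_octamer_mixture(self):
        c = np.zeros(16)
        c[0] = 0.5
        c[7] = 0.5
        assert n_ave(MassDistribution(c)) == pytest.approx(4.5)

    def test_pure_octamer(self):
        c = np.zeros(16)
        c[7] = 1.0
        assert n_ave(MassDistribution(c)) == 8.0

    def test_overflow_counts_with_nmax(self):
        c = np.zeros(10)
        assert n_ave(MassDistribution(c, overflow=1.0)) == 10.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            n_ave(MassDistribution(np.zeros(4)))


class TestDiffusionLimit:
    def test_published_conditions(self):
        # glycerol/water at 297 K and 2.0 cP
        r0 = diffusion_limited_r0(PhysicalConditions(297.0, 2.0))
        assert r0 == pytest.approx(8.3e5, rel=0.02)

    def test_viscosity_scaling_is_exact(self):
        a = diffusion_limited_r0(PhysicalConditions(297.0, 1.0))
        b = diffusion_limited_r0(PhysicalConditions(297.0, 2.0))
        assert a == pytest.approx(2 * b, rel=1e-14)
        assert a == pytest.approx(1.66e6, rel=0.02)


class TestConstantKernelEstimate:
    def test_published_discussion_figure(self):
        # n_ave ~ 2 at 20 ms and 1.5 mM implies tens of mM^-1 s^-1
        k = constant_kernel_rate_estimate(2.0, 0.02, 1.5)
        assert 10 < k < 100
        assert k == pytest.approx(33.3, rel=0.01)

    def test_linearization_and_concentration_scaling(self):
        eps = 1e-6
        k = constant_kernel_rate_estimate(1 + eps, 0.01, 1.0)
        assert k == pytest.approx(eps / 0.01, rel=1e-9)
        assert constant_kernel_rate_estimate(2.0, 0.02, 3.0) == pytest.approx(
            constant_kernel_rate_estimate(2.0, 0.02, 1.5) / 2
        )

    def test_self_doubled_convention_halves(self):
        std = constant_kernel_rate_estimate(2.0, 0.02, 1.5)
        alt = constant_kernel_rate_estimate(2.0, 0.02, 1.5, convention="self-doubled")
        assert alt == pytest.approx(std / 2)

    def test_rejects_unit_mean_size(self):
        with pytest.raises(ValueError):
            constant_kernel_rate_estimate(1.0, 0.02, 1.5)


class TestSimulation:
    def test_zero_rate_leaves_distribution_unchanged(self):
        init = monomer_distribution(1.5, 32)
        traj = simulate_coagulation(init, KernelParams(r0=0.0), np.linspace(0, 10, 5))
        assert np.allclose(traj.concentrations, init.c)
        assert np.allclose(traj.overflow, 0.0)

    def test_mass_conservation(self, best_fit_kernel):
        init = monomer_distribution(1.5, 512)
        times = np.logspace(-3, np.log10(600.0), 40)
        traj = simulate_coagulation(init, best_fit_kernel, times)
        drift = np.abs(traj.total_mass() - 1.5) / 1.5
        assert drift.max() < 1e-6

    def test_initial_state_preserved(self, best_fit_kernel):
        init = monomer_distribution(1.5, 64)
        traj = simulate_coagulation(init, best_fit_kernel, np.array([0.0, 0.1, 1.0]))
        assert np.allclose(traj.concentrations[0], init.c)

    def test_n_ave_monotone_from_monomeric_start(self, best_fit_kernel):
        init = monomer_distribution(1.5, 256)
        traj = simulate_coagulation(init, best_fit_kernel, np.logspace(-2, 2, 30))
        nave = traj.n_ave_series()
        assert np.all(np.diff(nave) >= -1e-9)

    def test_separable_matches_direct_rhs(self):
        params = KernelParams(r0=0.01, e0=50.0, nth=8.0)
        nmax = 64
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.random(nmax), [0.05]])
        d_sep = _SeparableRHS(nmax, params)(0.0, y)
        d_dir = _DirectRHS(nmax, kernel_matrix(nmax, params))(0.0, y)
        scale = np.max(np.abs(d_dir))
        assert np.max(np.abs(d_sep - d_dir)) / scale < 1e-10

    @pytest.mark.parametrize("x", [0.5, 2.0])
    def test_concentration_time_scaling_invariance(self, x):
        # c -> x c together with t -> t / x leaves the equations invariant
        params = KernelParams(r0=0.02, e0=20.0, nth=8.0)
        times = np.logspace(-2, np.log10(50.0), 20)
        base = simulate_coagulation(monomer_distribution(1.0, 256), params, x * times)
        scaled = simulate_coagulation(monomer_distribution(x * 1.0, 256), params, times)
        assert np.allclose(scaled.concentrations, x * base.concentrations, rtol=1e-4, atol=1e-9)

    def test_bimolecular_closed_form_with_capped_constant_kernel(self):
        # only monomer + monomer -> dimer allowed: dc1/dt = -2 K c1^2
        K = 2.0

        def capped(n, m):
            return np.where(n + m > 2, 0.0, K)

        init = monomer_distribution(1.0, 4)
        times = np.linspace(0, 1.0, 8)
        traj = simulate_coagulation(init, KernelParams(r0=1.0), times, kernel_override=capped)
        c1 = traj.concentrations[:, 0]
        assert np.allclose(c1, 1.0 / (1 + 2 * K * times), rtol=1e-6)

    def test_overflow_conserves_mass_and_warns(self):
        init = monomer_distribution(1.0, 8)
        params = KernelParams(r0=1.0, e0=10.0, nth=4.0)
        with pytest.warns(UserWarning):
            traj = simulate_coagulation(init, params, np.linspace(0, 5, 6))
        assert traj.overflow[-1] > 0
        assert np.abs(traj.total_mass() - 1.0).max() < 1e-6
        assert traj.meta["overflow_warning"]

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_coagulation(
                monomer_distribution(1.0, 8), KernelParams(r0=1.0), np.array([1.0, 0.5])
            )


class TestStochasticOracle:
    def test_zero_rate_keeps_monomers(self, small_monomer_start):
        res = stochastic_oracle(small_monomer_start, KernelParams(r0=0.0), 10.0, 500, seed=3)
        assert np.all(res["final_sizes"] == 1)
        assert res["n_ave"][-1] == 1.0

    def test_constant_kernel_matches_ode(self, constant_kernel):
        init = monomer_distribution(1.0, 256)
        checkpoints = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        traj = simulate_coagulation(
            init, KernelParams(r0=1.0), checkpoints, kernel_override=constant_kernel
        )
        ode = traj.n_ave_series()
        runs = np.array(
            [
                stochastic_oracle(
                    init,
                    KernelParams(r0=1.0),
                    0.5,
                    10_000,
                    seed=s,
                    checkpoints=checkpoints,
                    kernel=constant_kernel,
                )["n_ave"]
                for s in range(20)
            ]
        )
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        assert np.all(np.abs(mean - ode) <= 3 * se)

    def test_enhanced_kernel_matches_ode(self):
        params = KernelParams(r0=0.5, e0=10.0, nth=8.0)
        init = monomer_distribution(1.0, 128)
        checkpoints = np.array([0.05, 0.1, 0.2, 0.35, 0.5])
        traj = simulate_coagulation(init, params, checkpoints)
        ode = traj.n_ave_series()
        runs = np.array(
            [
                stochastic_oracle(
                    init, params, 0.5, 10_000, seed=100 + s, checkpoints=checkpoints
                )["n_ave"]
                for s in range(20)
            ]
        )
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        assert np.all(np.abs(mean - ode) <= 3 * se)

    def test_capped_dimerization_matches_closed_form(self, constant_kernel):
        # n_ave(t) = 2 - c1/c0 with c1 = c0 / (1 + 2 K c0 t)
        init = monomer_distribution(1.0, 2)
        K = constant_kernel.K
        t_check = np.array([0.5, 1.0])
        runs = np.array(
            [
                stochastic_oracle(
                    init,
                    KernelParams(r0=1.0),
                    1.0,
                    2000,
                    seed=s,
                    checkpoints=t_check,
                    kernel=constant_kernel,
                    size_cap=2,
                )["n_ave"]
                for s in range(20)
            ]
        )
        expected = 2.0 - 1.0 / (1 + 2 * K * t_check)
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        assert np.all(np.abs(mean - expected) <= 3 * se)

    def test_too_few_particles_rejected(self, small_monomer_start):
        with pytest.raises(ValueError):
            stochastic_oracle(small_monomer_start, KernelParams(r0=1.0), 1.0, 50)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"r0": -1.0}, {"r0": 1.0, "e0": 0.5}, {"r0": 1.0, "nth": 0.0}]
    )
    def test_kernel_params_invariants(self, kwargs):
        with pytest.raises(ValueError):
            KernelParams(**kwargs)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            MassDistribution(np.array([1.0, -0.1]))
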