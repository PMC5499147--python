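import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from autoimmsim import (
    DiffusionConfig,
    ParameterError,
    DegenerateParameterError,
    effective_diffusion_w,
    equilibrium_fractions,
    fundamental_solution,
    linear_fractions,
    perturbed_constant,
    reduced_constant,
    simulate_full,
    simulate_reduced,
)


def gaussian_ic(cfg, amp=1e-3, center=None, sigma=None):
    x = cfg.x_grid
    center = cfg.L / 2.0 if center is None else center
    sigma = cfg.L / 20.0 if sigma is None else sigma
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))


class TestConfig:
    def test_derived_quantities(self, diffusion_cfg):
        cfg = diffusion_cfg
        assert cfg.K_M == pytest.approx(cfg.kM_minus / cfg.kM_plus)
        assert cfg.gamma_M == pytest.approx(cfg.B_M / cfg.K_M)
        assert cfg.lam == pytest.approx(1.0 + cfg.gamma_M + cfg.gamma_N)
        assert cfg.d_hat == pytest.approx(
            (cfg.D0 + cfg.DM * cfg.gamma_M + cfg.DN * cfg.gamma_N) / cfg.lam
        )

    @pytest.mark.parametrize("kw", [dict(L=0.0), dict(n_x=2), dict(D0=0.0),
                                    dict(kM_plus=-1.0), dict(B_M=-0.5)])
    def test_validation(self, kw):
        base = dict(L=1.0, n_x=50, D0=1.0, DM=0.1, DN=0.05,
                    kM_plus=500.0, kM_minus=1000.0, kN_plus=500.0,
                    kN_minus=1000.0, B_M=4.0, B_N=2.0)
        base.update(kw)
        with pytest.raises(ParameterError):
            DiffusionConfig(**base)


class TestAlgebraicReduction:
    @given(gm=st.floats(0.0, 20.0), gn=st.floats(0.0, 20.0),
           D0=st.floats(0.01, 5.0), DM=st.floats(0.01, 5.0),
           DN=st.floats(0.01, 5.0))
    def test_convex_combination(self, gm, gn, D0, DM, DN):
        d = reduced_constant(gm, gn, D0, DM, DN)
        assert min(D0, DM, DN) - 1e-12 <= d <= max(D0, DM, DN) + 1e-12

    def test_no_buffering_recovers_free_diffusion(self):
        assert reduced_constant(0.0, 0.0, 1.3, 0.1, 0.05) == pytest.approx(1.3)

    def test_composite_field_coefficient(self):
        # with linear buffering, dC/dw = gamma/lam, and the w-equation
        # coefficient equals the reduced constant
        gm, gn, D0, DM, DN = 2.0, 1.0, 1.0, 0.1, 0.05
        lam = 1.0 + gm + gn
        got = effective_diffusion_w(gm / lam, gn / lam, D0, DM, DN)
        assert got == pytest.approx(reduced_constant(gm, gn, D0, DM, DN))

    def test_linear_vs_equilibrium_fractions_small_u(self, diffusion_cfg):
        cfg = diffusion_cfg
        u = np.linspace(0.0, 1e-4, 20)
        eqM, eqN = equilibrium_fractions(u, cfg.B_M, cfg.K_M, cfg.B_N, cfg.K_N)
        linM, linN, w = linear_fractions(u, cfg.gamma_M, cfg.gamma_N)
        np.testing.assert_allclose(eqM, linM, rtol=1e-4)
        np.testing.assert_allclose(eqN, linN, rtol=1e-4)
        np.testing.assert_allclose(w, u + linM + linN, rtol=1e-12)

    def test_negative_u_rejected(self):
        with pytest.raises(ParameterError):
            equilibrium_fractions(np.array([-1.0]), 1.0, 1.0, 1.0, 1.0)


class TestPerturbation:
    def test_shift_vanishes_at_zero(self, diffusion_cfg):
        cfg = diffusion_cfg
        p = perturbed_constant(0.0, cfg.d_hat, cfg.lam, cfg.DN, cfg.K_N)
        assert p.delta_exact == 0.0 and p.delta_first_order == 0.0
        assert p.d_tilde == pytest.approx(cfg.d_hat)

    def test_first_order_agreement_small_eps(self, diffusion_cfg):
        cfg = diffusion_cfg
        p = perturbed_constant(1e-6, cfg.d_hat, cfg.lam, cfg.DN, cfg.K_N)
        assert p.delta_exact == pytest.approx(p.delta_first_order, rel=1e-5)

    def test_gap_is_second_order(self, diffusion_cfg):
        cfg = diffusion_cfg
        g = []
        for eps in (0.4, 0.2):
            p = perturbed_constant(eps, cfg.d_hat, cfg.lam, cfg.DN, cfg.K_N)
            g.append(p.delta_exact - p.delta_first_order)
        assert 3.2 < g[0] / g[1] < 4.8

    def test_literal_variant_differs(self, diffusion_cfg):
        cfg = diffusion_cfg
        a = perturbed_constant(0.2, cfg.d_hat, cfg.lam, cfg.DN, cfg.K_N)
        b = perturbed_constant(0.2, cfg.d_hat, cfg.lam, cfg.DN, cfg.K_N,
                               paper_literal=True)
        assert a.delta_first_order != pytest.approx(b.delta_first_order)

    def test_excessive_perturbation_rejected(self, diffusion_cfg):
        cfg = diffusion_cfg
        with pytest.raises(DegenerateParameterError):
            perturbed_constant(cfg.lam * cfg.K_N * 1.01, cfg.d_hat, cfg.lam,
                               cfg.DN, cfg.K_N)


class TestFundamentalSolution:
    def test_normalization(self):
        x = np.linspace(-50, 50, 20001)
        for D, t in [(0.3, 0.5), (1.0, 2.0)]:
            mass = np.trapezoid(fundamental_solution(t, x, D), x)
            assert mass == pytest.approx(1.0, abs=1e-8)

    def test_variance_growth(self):
        x = np.linspace(-50, 50, 20001)
        D, t = 0.4, 1.5
        g = fundamental_solution(t, x, D)
        var = np.trapezoid(x * x * g, x)
        assert var == pytest.approx(2.0 * D * t, rel=1e-8)

    def test_invalid_args(self):
        with pytest.raises(ParameterError):
            fundamental_solution(1.0, 0.0, -1.0)
        with pytest.raises(ParameterError):
            fundamental_solution(0.0, 0.0, 1.0)


class TestSimulation:
    def test_mass_conservation_zero_flux(self, diffusion_cfg):
        cfg = diffusion_cfg
        u0 = gaussian_ic(cfg)
        snaps = simulate_full(cfg, u0, np.linspace(0.0, 0.05, 4))
        m0 = snaps[0].mass_w()
        for s in snaps[1:]:
            assert abs(s.mass_w() - m0) <= 1e-8 * max(1.0, abs(m0))

    def test_reduction_agrees_within_tolerance(self, diffusion_cfg):
        cfg = diffusion_cfg
        u0 = gaussian_ic(cfg)
        t_eval = np.linspace(0.0, 0.05, 6)
        snaps = simulate_full(cfg, u0, t_eval)
        red = simulate_reduced(cfg, u0, t_eval)
        for s, r in zip(snaps[1:], red[1:]):
            err = np.linalg.norm(s.u - r) / np.linalg.norm(s.u)
            assert err <= 0.05

    def test_reduced_matches_heat_kernel_variance(self):
        cfg = DiffusionConfig(
            L=4.0, n_x=400, D0=1.0, DM=0.1, DN=0.05,
            kM_plus=500.0, kM_minus=1000.0, kN_plus=500.0, kN_minus=1000.0,
            B_M=4.0, B_N=2.0,
        )
        x = cfg.x_grid
        s0 = 0.1
        u0 = 1e-3 * np.exp(-((x - 2.0) ** 2) / (2.0 * s0 ** 2))
        t_eval = np.array([0.0, 0.2])
        out = simulate_reduced(cfg, u0, t_eval)
        u = out[-1]
        m0 = np.trapezoid(u, x)
        mu = np.trapezoid(x * u, x) / m0
        var = np.trapezoid((x - mu) ** 2 * u, x) / m0
        assert var == pytest.approx(s0 ** 2 + 2.0 * cfg.d_hat * 0.2, rel=0.01)

    def test_influx_boundary_adds_mass(self, diffusion_cfg):
        cfg = DiffusionConfig(**{**diffusion_cfg.to_dict(), "flux_left": 1e-3})
        u0 = gaussian_ic(cfg)
        snaps = simulate_full(cfg, u0, np.linspace(0.0, 0.02, 3))
        assert snaps[-1].mass_w() > snaps[0].mass_w()

    def test_bad_initial_shape(self, diffusion_cfg):
        with pytest.raises(ParameterError):
            simulate_full(diffusion_cfg, np.zeros(7), np.linspace(0, 0.01, 2))
        with pytest.raises(ParameterError):
            simulate_reduced(diffusion_cfg, np.zeros(7), np.linspace(0, 0.01, 2))
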