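import numpy as np
import pytest
from hypothesis import given, strategies as st

import autoimmsim as ai
from autoimmsim import (
    assemble_populations,
    collateral_reduced,
    count_interior_extrema,
    derive_reduced_constants,
    dose_sweep,
    has_rebound,
    health_reduced,
    pushpull_decomposition,
    seeded_parameter_set,
)


class TestAssembly:
    def test_conservation_identity(self, fx, t_grid):
        curves = assemble_populations(t_grid, fx.sp, fx.psi, fx.ds, fx.T)
        np.testing.assert_allclose(curves.total, fx.T, atol=1e-9 * fx.T)

    def test_initial_values(self, fx, t_grid, reduced_constants):
        c = reduced_constants
        curves = assemble_populations(t_grid, fx.sp, fx.psi, fx.ds, fx.T)
        assert curves.H[0] == pytest.approx(fx.T - c.lam * fx.sp.V0, rel=1e-14)
        assert curves.C[0] == pytest.approx(c.lam1 * fx.sp.V0, rel=1e-14)
        ist = ai.derive_initial_state(fx.sp)
        # M(0), N(0) = dose split plus the instantaneous signal response
        j0, k0 = ist.J0, ist.K0
        assert curves.M[0] == pytest.approx(
            ist.M0 + fx.psi.H2j * j0 + fx.psi.H2k * k0, rel=1e-12
        )
        assert curves.N[0] == pytest.approx(
            ist.N0 + fx.psi.H3j * j0 + fx.psi.H3k * k0, rel=1e-12
        )

    def test_zero_dose_is_flat_health(self, fx, t_grid):
        curves = assemble_populations(
            t_grid, fx.sp.with_dose(0.0), fx.psi, fx.ds, fx.T
        )
        np.testing.assert_allclose(curves.H, fx.T, atol=1e-12 * fx.T)
        np.testing.assert_allclose(curves.C, 0.0, atol=1e-12 * fx.T)

    def test_grid_validation(self, fx):
        with pytest.raises(ValueError):
            assemble_populations(np.array([2.0, 1.0]), fx.sp, fx.psi, fx.ds, fx.T)


class TestReducedForms:
    def test_health_matches_assembly(self, fx, t_grid, reduced_constants):
        curves = assemble_populations(t_grid, fx.sp, fx.psi, fx.ds, fx.T)
        H = health_reduced(t_grid, fx.sp, fx.ds, reduced_constants)
        assert np.max(np.abs(H - curves.H)) <= 1e-10 * fx.T

    def test_collateral_matches_assembly(self, fx, t_grid, reduced_constants):
        curves = assemble_populations(t_grid, fx.sp, fx.psi, fx.ds, fx.T)
        C = collateral_reduced(t_grid, fx.sp, fx.ds, reduced_constants)
        assert np.max(np.abs(C - curves.C)) <= 1e-10 * fx.T

    def test_matches_on_seeded_sets(self, rng, t_grid):
        for _ in range(5):
            sp, psi, ds, T = seeded_parameter_set(rng)
            c = derive_reduced_constants(sp, psi, ds, T)
            curves = assemble_populations(t_grid, sp, psi, ds, T)
            H = health_reduced(t_grid, sp, ds, c)
            C = collateral_reduced(t_grid, sp, ds, c)
            scale = max(T, float(np.max(np.abs(curves.H))))
            assert np.max(np.abs(H - curves.H)) <= 1e-10 * scale
            assert np.max(np.abs(C - curves.C)) <= 1e-10 * scale

    def test_literal_phase_variant_breaks_identity(self, fx, t_grid, reduced_constants):
        """Negative control: the historical constant phase is inconsistent."""
        curves = assemble_populations(t_grid, fx.sp, fx.psi, fx.ds, fx.T)
        H_lit = health_reduced(
            t_grid, fx.sp, fx.ds, reduced_constants, paper_literal=True
        )
        assert np.max(np.abs(H_lit - curves.H)) > 1e-3 * fx.T

    def test_literal_variant_breaks_zero_dose_baseline(self, fx, reduced_constants):
        sp0 = fx.sp.with_dose(0.0)
        c0 = derive_reduced_constants(sp0, fx.psi, fx.ds, fx.T)
        t = np.array([0.0, 1.0])
        np.testing.assert_allclose(
            health_reduced(t, sp0, fx.ds, c0), fx.T, atol=1e-12 * fx.T
        )
        # the consistent form is exact at V0=0; literal one only differs for V0>0,
        # where its t=0 value misses T - lam*V0
        H_lit0 = health_reduced(np.array([0.0]), fx.sp, fx.ds, reduced_constants,
                                paper_literal=True)
        assert abs(H_lit0[0] - (fx.T - reduced_constants.lam * fx.sp.V0)) > 1e-6


class TestPushPull:
    def test_decomposition_reconstructs_health(self, fx, t_grid, reduced_constants):
        parts = pushpull_decomposition(t_grid, fx.sp, fx.ds, reduced_constants)
        H = health_reduced(t_grid, fx.sp, fx.ds, reduced_constants)
        np.testing.assert_allclose(
            fx.T + parts["decay"] + parts["delta"], H, atol=1e-10 * fx.T
        )
        np.testing.assert_allclose(parts["gain"],
                                   parts["delta"] / reduced_constants.s1 * reduced_constants.s1,
                                   atol=1e-12 * fx.T)

    def test_decay_is_monotone_nonincreasing(self, fx, t_grid, reduced_constants):
        parts = pushpull_decomposition(t_grid, fx.sp, fx.ds, reduced_constants)
        assert np.all(np.diff(parts["decay"]) <= 1e-15)


class TestExtremaCounting:
    def test_sine_extrema(self):
        t = np.linspace(0.0, 4.0 * np.pi, 2001)
        assert count_interior_extrema(np.sin(t), tol=1e-12) == 4

    def test_monotone_has_none(self):
        assert count_interior_extrema(np.linspace(0, 1, 100), tol=1e-12) == 0

    def test_plateau_counts_once(self):
        y = np.concatenate([np.linspace(0, 1, 10), np.ones(20),
                            np.linspace(1, 0, 10)])
        assert count_interior_extrema(y, tol=1e-12) == 1

    @given(n=st.integers(0, 6))
    def test_counts_match_construction(self, n):
        t = np.linspace(0.0, (n + 1) * np.pi, 400 * (n + 2))
        assert count_interior_extrema(np.cos(t), tol=1e-12) == n


class TestRebound:
    def test_v_shape_rebounds(self):
        H = np.concatenate([np.linspace(100, 50, 50), np.linspace(50, 80, 50)])
        assert has_rebound(H, 100.0, rebound_frac=0.01, tol=1e-9)

    def test_monotone_decline_does_not(self):
        H = np.linspace(100, 40, 100)
        assert not has_rebound(H, 100.0, rebound_frac=0.01, tol=1e-9)

    def test_tiny_recovery_below_threshold(self):
        H = np.concatenate([np.linspace(100, 50, 50),
                            np.linspace(50, 50.5, 50)])
        assert not has_rebound(H, 100.0, rebound_frac=0.01, tol=1e-9)


class TestDoseSweep:
    def test_summaries_cover_grid(self, fx, t_grid):
        doses = np.arange(0.0, 11.0, 1.0)
        out = dose_sweep(doses, t_grid, fx.sp, fx.psi, fx.ds, fx.T)
        assert [s.V0 for s in out] == list(doses)

    def test_zero_dose_is_full_health(self, fx, t_grid):
        s = dose_sweep(np.array([0.0]), t_grid, fx.sp, fx.psi, fx.ds, fx.T)[0]
        assert s.min_health_pct == pytest.approx(100.0)
        assert not s.rebound

    def test_window_restricts_collateral(self, fx, t_grid):
        full = dose_sweep(np.array([5.0]), t_grid, fx.sp, fx.psi, fx.ds, fx.T)[0]
        late = dose_sweep(np.array([5.0]), t_grid, fx.sp, fx.psi, fx.ds, fx.T,
                          window=(4.0, 5.0))[0]
        assert late.max_collateral <= full.max_collateral + 1e-12

    def test_empty_window_rejected(self, fx, t_grid):
        with pytest.raises(ValueError):
            dose_sweep(np.array([5.0]), t_grid, fx.sp, fx.psi, fx.ds, fx.T,
                       window=(9.0, 10.0))
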