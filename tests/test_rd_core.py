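"""Engine tests: diffusion stencil, Monod growth, operator splitting,
batch runs and the well-mixed limit."""

import numpy as np
import pytest

from zetasim import (Domain, FullParams, SimState,
                     StabilityError, StepControl, default_step_control,
                     diffuse_step, growth_step, initial_state,
                     run_until_consumed, run_well_mixed,
                     seed_random_founders, stability_dt, step, to_scaled)
from zetasim.protocols import FounderMap


def unit_domain(n=11, boundary="torus"):
    return Domain(nx=n, ny=n, dx=1.0, boundary=boundary)


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        dom = unit_domain()
        f = np.full(dom.shape, 3.7)
        g = diffuse_step(f, 1.0, stability_dt(1.0, 1.0), dom)
        np.testing.assert_allclose(g, f, rtol=1e-14)

    @pytest.mark.parametrize("boundary", ["torus", "no_flux"])
    def test_point_mass_one_step_stencil(self, boundary):
        dom = unit_domain(boundary=boundary)
        f = np.zeros(dom.shape)
        f[5, 5] = 2.5
        dt = stability_dt(1.0, 1.0)
        g = diffuse_step(f, 1.0, dt, dom)
        assert g[5, 5] == pytest.approx(2.5 * (1 - 4 * dt), rel=1e-14)
        for j, i in ((4, 5), (6, 5), (5, 4), (5, 6)):
            assert g[j, i] == pytest.approx(2.5 * dt, rel=1e-14)

    @pytest.mark.parametrize("boundary", ["torus", "no_flux"])
    def test_mass_conserved_over_many_steps(self, boundary, rng):
        dom = unit_domain(boundary=boundary)
        f = rng.uniform(0.0, 10.0, dom.shape)
        total = f.sum()
        dt = stability_dt(1.0, 1.0)
        for _ in range(200):
            f = diffuse_step(f, 1.0, dt, dom)
        assert f.sum() == pytest.approx(total, rel=1e-12)
        assert f.min() >= 0

    def test_unstable_dt_rejected_not_substepped(self):
        dom = unit_domain()
        with pytest.raises(StabilityError):
            diffuse_step(np.ones(dom.shape), 1.0, 1.01 * stability_dt(1.0, 1.0),
                         dom)

    def test_point_release_matches_heat_kernel(self):
        # free diffusion of a point mass on a large torus vs the analytic
        # Gaussian kernel, compared where the kernel is non-negligible
        dom = unit_domain(n=81)
        D, m = 1.0, 5.0
        f = np.zeros(dom.shape)
        f[40, 40] = m
        dt = stability_dt(1.0, D)
        n_steps = 150
        for _ in range(n_steps):
            f = diffuse_step(f, D, dt, dom)
        T = n_steps * dt
        jj, ii = np.meshgrid(np.arange(81), np.arange(81), indexing="ij")
        r2 = (ii - 40.0) ** 2 + (jj - 40.0) ** 2
        kernel = m / (4 * np.pi * D * T) * np.exp(-r2 / (4 * D * T))
        mask = kernel > 1e-3 * kernel.max()
        rel = np.abs(f[mask] - kernel[mask]) / kernel.max()
        assert rel.max() < 0.02


class TestGrowth:
    def test_no_resource_no_growth(self):
        B = np.array([2.0, 3.0])
        B2, R2 = growth_step(B, 0.0, np.array([0.2, 0.1]), 1.0, 1.0, 0.5)
        np.testing.assert_array_equal(B2, B)
        assert R2 == 0.0

    def test_small_dt_matches_ode_right_hand_side(self):
        # dB/dt = mu*B*R/(R+k) = 0.1*100/101 at B=1, R=100, k=1
        dt = 1e-6
        B2, _ = growth_step(np.array([1.0]), 100.0, np.array([0.1]), 1.0,
                            1.0, dt)
        assert (B2[0] - 1.0) / dt == pytest.approx(0.1 * 100 / 101, rel=1e-5)

    def test_unit_yield_conserves_biomass_plus_resource(self, rng):
        B = rng.uniform(0, 5, (3, 8, 8))
        R = rng.uniform(0, 50, (8, 8))
        B2, R2 = growth_step(B, R, np.array([0.4, 0.2, 0.1]), 1.0, 1.0, 0.3)
        np.testing.assert_allclose(B2.sum(axis=0) + R2, B.sum(axis=0) + R,
                                   rtol=1e-10)

    def test_resource_never_negative_under_heavy_demand(self):
        # demand far exceeds supply: gain capped, R pinned at 0
        B2, R2 = growth_step(np.array([1000.0]), 0.5, np.array([1.0]), 1.0,
                             1.0, 1.0)
        assert R2 == pytest.approx(0.0, abs=1e-12)
        assert B2[0] == pytest.approx(1000.5, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            growth_step(np.array([-1.0]), 1.0, np.array([0.1]), 1, 1, 0.1)
        with pytest.raises(ValueError):
            growth_step(np.array([1.0]), -1.0, np.array([0.1]), 1, 1, 0.1)


class TestStep:
    def make_state(self, dom, rng, L=2):
        B = rng.uniform(0, 2, (L,) + dom.shape)
        R = rng.uniform(1, 100, dom.shape)
        return SimState(R_field=R, B_fields=B,
                        lineage_genotype=np.arange(L) % 2)

    def test_matches_manual_growth_then_diffusion(self, table_params, rng):
        dom = Domain(nx=3, ny=3, dx=0.5, boundary="torus")
        state = self.make_state(dom, rng)
        ctrl = default_step_control(table_params, dom)
        out = step(state, table_params, ctrl, dom)
        mu = np.asarray(table_params.mu)[state.lineage_genotype]
        B, R = growth_step(state.B_fields, state.R_field, mu,
                           table_params.k, table_params.lam, ctrl.dt)
        B = diffuse_step(B, table_params.D_B, ctrl.dt, dom)
        R = diffuse_step(R, table_params.D_R, ctrl.dt, dom)
        np.testing.assert_allclose(out.B_fields, B, rtol=1e-14)
        np.testing.assert_allclose(out.R_field, R, rtol=1e-14)
        assert out.t == pytest.approx(ctrl.dt)

    def test_no_resource_only_time_advances(self, table_params):
        dom = Domain(nx=5, ny=5, dx=0.5, boundary="torus")
        B = np.full((2,) + dom.shape, 1.3)
        state = SimState(R_field=np.zeros(dom.shape), B_fields=B,
                         lineage_genotype=np.array([0, 1]))
        ctrl = default_step_control(table_params, dom)
        out = step(state, table_params, ctrl, dom)
        np.testing.assert_allclose(out.B_fields, B, rtol=1e-13)
        assert out.t > 0

    def test_batch_monotonicity(self, table_params, rng):
        dom = unit_domain(7)
        state = self.make_state(dom, rng)
        ctrl = StepControl(dt=stability_dt(dom.dx, table_params.D_R))
        for _ in range(20):
            nxt = step(state, table_params, ctrl, dom)
            assert nxt.B_fields.sum() >= state.B_fields.sum() - 1e-12
            assert nxt.R_field.sum() <= state.R_field.sum() + 1e-12
            state = nxt


class TestRunUntilConsumed:
    def run_small(self, params, dom, fmap, frac=0.99):
        state = initial_state(fmap, dom, params.R0, track="genotype",
                              n_genotypes=len(params.mu))
        ctrl = default_step_control(params, dom, consumed_frac_stop=frac)
        return state, run_until_consumed(state, params, ctrl, dom)

    def test_stop_rule_and_conservation(self, small_torus):
        params = FullParams(D_B=1.8e-5, D_R=1.8e-2, mu=(0.22, 0.2), k=1.0,
                            lam=1.0, R0=100.0)
        fmap = seed_random_founders(5, small_torus, [0, 1, 1, 1, 1], 7)
        start, final = self.run_small(params, small_torus, fmap)
        initial_R = start.R_field.sum()
        assert final.R_field.sum() <= 0.01 * initial_R
        # unit yield: final biomass >= founders + 99% of the resource
        assert final.B_fields.sum() >= start.B_fields.sum() + 0.99 * initial_R
        # closed-system bookkeeping to high precision
        assert (final.B_fields.sum() + final.R_field.sum()) == pytest.approx(
            start.B_fields.sum() + initial_R, rel=1e-8)

    def test_all_zero_biomass_raises_after_max_steps(self, small_torus,
                                                     table_params):
        state = SimState(R_field=np.full(small_torus.shape, 10.0),
                         B_fields=np.zeros((1,) + small_torus.shape),
                         lineage_genotype=np.array([0]))
        ctrl = StepControl(dt=stability_dt(small_torus.dx, table_params.D_R),
                           max_steps=50)
        with pytest.raises(RuntimeError):
            run_until_consumed(state, table_params, ctrl, small_torus)

    def test_single_founder_symmetry_on_torus(self):
        # a lone centered founder: final fields invariant under the lattice
        # reflections fixing the founder
        dom = Domain(nx=11, ny=11, dx=0.4, boundary="torus")
        params = FullParams(D_B=1.8e-5, D_R=1.8e-2, mu=(0.3,), k=1.0,
                            lam=1.0, R0=50.0)
        fmap = FounderMap(ix=[5], iy=[5], genotype=[0])
        _, final = self.run_small(params, dom, fmap)
        B = final.B_fields[0]
        np.testing.assert_allclose(B, B[::-1, :], rtol=1e-10)
        np.testing.assert_allclose(B, B[:, ::-1], rtol=1e-10)
        np.testing.assert_allclose(B, B.T, rtol=1e-10)

    def test_grid_refinement_converges(self):
        # same 5 cm x 5 cm physical scenario at dx and dx/2: final genotype
        # frequencies agree within 1%
        params = FullParams(D_B=1.8e-5, D_R=1.8e-2, mu=(0.22, 0.2), k=1.0,
                            lam=1.0, R0=100.0)
        freqs = []
        for n in (20, 40):
            dom = Domain(nx=n, ny=n, dx=5.0 / n, boundary="torus")
            s = n // 20
            fmap = FounderMap(ix=[5 * s, 14 * s], iy=[5 * s, 12 * s],
                              genotype=[0, 1])
            state = initial_state(fmap, dom, params.R0, track="genotype",
                                  n_genotypes=2)
            ctrl = default_step_control(params, dom)
            final = run_until_consumed(state, params, ctrl, dom)
            totals = final.genotype_totals(2)
            freqs.append(totals[0] / totals.sum())
        assert abs(freqs[1] - freqs[0]) < 0.01


class TestWellMixed:
    def test_equal_rates_equal_outcome(self):
        B = run_well_mixed(np.array([3.0, 3.0]), 500.0,
                           np.array([0.2, 0.2]), 1.0, 1.0)
        assert B[0] == pytest.approx(B[1], rel=1e-10)

    def test_log_fold_change_ratio_is_growth_rate_ratio(self):
        B0 = np.array([1.0, 48.0])
        B = run_well_mixed(B0, 10000.0, np.array([0.11, 0.10]), 1.0, 1.0)
        lfc = np.log(B / B0)
        assert lfc[0] / lfc[1] == pytest.approx(1.1, abs=1e-6)

    def test_final_total_honors_stop_rule(self):
        B0, R0 = np.array([2.0, 5.0]), 1000.0
        B = run_well_mixed(B0, R0, np.array([0.3, 0.2]), 1.0, 1.0)
        assert B.sum() == pytest.approx(B0.sum() + 0.99 * R0, rel=1e-8)


class TestScaledFullEquivalence:
    def test_fields_agree_after_unit_conversion(self, small_torus):
        full = FullParams(D_B=1.8e-5, D_R=1.8e-2, mu=(0.165, 0.15), k=2.0,
                          lam=0.5, R0=100.0)
        scaled, tr = to_scaled(full)
        dom_s = Domain(nx=small_torus.nx, ny=small_torus.ny,
                       dx=small_torus.dx / tr.x_c, boundary="torus")
        fmap = seed_random_founders(3, small_torus, [0, 1, 1], 42)
        st_f = initial_state(fmap, small_torus, full.R0, track="genotype",
                             n_genotypes=2)
        st_s = initial_state(fmap, dom_s, scaled.R0_hat, track="genotype",
                             n_genotypes=2, founder_biomass=1.0 / tr.B_c)
        fin_f = run_until_consumed(st_f, full,
                                   default_step_control(full, small_torus),
                                   small_torus)
        fin_s = run_until_consumed(st_s, scaled,
                                   default_step_control(scaled, dom_s), dom_s)
        scale_B = fin_f.B_fields.max()
        assert np.abs(fin_s.B_fields * tr.B_c - fin_f.B_fields).max() \
            < 1e-6 * scale_B
        assert np.abs(fin_s.R_field * tr.R_c - fin_f.R_field).max() \
            < 1e-6 * max(fin_f.R_field.max(), 1e-9)
        assert fin_s.t == pytest.approx(fin_f.t / tr.t_c, rel=1e-6)
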