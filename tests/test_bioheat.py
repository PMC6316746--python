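import dataclasses

import numpy as np
import pytest

from mammotherm import (
    BoundarySpec,
    ConvergenceError,
    TissueProps,
    assemble_steady,
    build_disc_mesh,
    build_domain,
    build_mesh,
    build_strip_mesh,
    energy_balance,
    mirror_domain,
    perfused_slab_oracle,
    solve_steady,
    solve_transient,
)
from mammotherm.geometry import HEALTHY, TUMOR


def uniform_props(**kw):
    base = dict(k=0.48, rho=1100.0, c=3300.0, q_met=0.0, omega_b=0.0, T_a=300.0)
    base.update(kw)
    return TissueProps(**base)


class TestAssembly:
    def test_constant_solves_laplace(self):
        # every boundary datum at 300 K, no sources or sinks -> T = 300
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        bc = BoundarySpec(h_f=15.0, epsilon=0.5, T_f=300.0, T_core=300.0)
        field = solve_steady(grid, {HEALTHY: uniform_props()}, bc)
        assert np.nanmax(np.abs(field.values - 300.0)) < 1e-8

    def test_interior_row_sums_vanish(self):
        # conservative flux stencil: conduction rows sum to zero for cells
        # with four interior neighbours
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        system = assemble_steady(grid, {HEALTHY: uniform_props()}, BoundarySpec())
        rowsum = np.asarray(system.cond.sum(axis=1)).ravel()
        # pick a deep interior cell: centre of the semicircle bulk
        j = grid.ny // 2
        i = grid.nx // 2
        assert grid.region[j, i] == HEALTHY
        assert abs(rowsum[system.index[j, i]]) < 1e-12

    def test_mirror_symmetric_assembly(self):
        # with the tumor on the y-axis the system is invariant under the
        # x-reflection permutation of unknowns
        spec = build_domain(40, (0, 10), 3)
        grid = build_mesh(spec, 1.0)
        props = {HEALTHY: uniform_props(omega_b=1e-4), TUMOR: uniform_props(q_met=1e4)}
        system = assemble_steady(grid, props, BoundarySpec())
        # permutation: unknown at (j, i) <-> unknown at (j, nx-1-i)
        perm = np.full(system.n, -1, dtype=np.int64)
        jj, ii = np.nonzero(grid.interior_mask)
        perm[system.index[jj, ii]] = system.index[jj, grid.nx - 1 - ii]
        assert np.all(perm >= 0)
        T_s = np.full(system.surf_idx.shape, 300.0)
        A = system.matrix(T_s)
        b = system.rhs(T_s)
        rng = np.random.default_rng(0)
        v = rng.normal(size=system.n)
        lhs = (A @ v)[perm]
        rhs = A @ v[perm]
        assert np.allclose(lhs, rhs, atol=1e-10)
        assert np.allclose(b[perm], b, atol=1e-12)

    def test_missing_region_props_rejected(self):
        grid = build_mesh(build_domain(40, (0, 10), 3), 1.0)
        with pytest.raises(ValueError, match="TUMOR"):
            assemble_steady(grid, {HEALTHY: uniform_props()}, BoundarySpec())

    def test_ill_posed_system_rejected(self):
        grid = build_disc_mesh(20, 1.0)
        bc = BoundarySpec(h_f=0.0, epsilon=0.0)
        with pytest.raises(ValueError, match="ill-posed"):
            assemble_steady(grid, {HEALTHY: uniform_props()}, bc)


class TestSteadySolve:
    def test_insulated_surface_gives_uniform_core_temperature(self):
        grid = build_mesh(build_domain(40, (0, 0), 0), 1.0)
        bc = BoundarySpec(h_f=0.0, epsilon=0.0, T_core=309.5)
        field = solve_steady(grid, {HEALTHY: uniform_props()}, bc)
        assert np.nanmax(np.abs(field.values - 309.5)) < 1e-8
        assert field.meta["residual"] < 1e-8

    def test_strip_matches_perfused_slab_closed_form(self):
        L = 60.0
        props = TissueProps(k=0.48, omega_b=1e-4, rho_b=1100.0, c_b=3300.0, T_a=293.0)
        oracle = perfused_slab_oracle(L, 0.48, 1e-4, 1100.0, 3300.0, 309.5, 293.0)
        grid = build_strip_mesh(L, 1.0, 0.25)
        bc = BoundarySpec(h_f=0.0, epsilon=0.0, T_f=293.0, T_core=309.5)
        field = solve_steady(grid, {HEALTHY: props}, bc)
        exact = oracle.evaluate(grid.y)
        err = np.abs(field.values[:, 0] - exact) / (309.5 - 293.0)
        assert err.max() < 0.005

    def test_metabolic_source_exceeds_core_with_insulating_boundary(self):
        # a positive tumor source under a (nearly) insulating skin must push
        # the interior above the core temperature somewhere near the tumor
        spec = build_domain(40, (0, 15), 4)
        grid = build_mesh(spec, 1.0)
        props = {
            HEALTHY: uniform_props(omega_b=0.0),
            TUMOR: uniform_props(q_met=5e4, omega_b=0.0),
        }
        bc = BoundarySpec(h_f=1e-6, epsilon=0.0, T_f=293.0, T_core=309.5)
        field = solve_steady(grid, props, bc)
        assert np.nanmax(field.values) > 309.5

    def test_maximum_principle_source_free(self, healthy, bc):
        grid = build_mesh(build_domain(60, (0, 0), 0), 1.0)
        field = solve_steady(grid, {HEALTHY: healthy}, bc)
        lo = min(bc.T_core, bc.T_f, healthy.T_a)
        hi = max(bc.T_core, bc.T_f, healthy.T_a)
        vals = field.interior_values()
        assert vals.min() >= lo - 1e-9
        assert vals.max() <= hi + 1e-9

    def test_energy_balance(self, coarse_tumor_solution):
        _, field = coarse_tumor_solution
        audit = energy_balance(field)
        assert audit["relative_imbalance"] < 1e-3
        assert audit["base_in_W"] > 0

    def test_emissivity_monotonicity(self, healthy, bc):
        grid = build_mesh(build_domain(40, (0, 0), 0), 1.0)
        surfaces = []
        for eps in (0.0, 0.5, 0.98):
            field = solve_steady(
                grid, {HEALTHY: healthy}, dataclasses.replace(bc, epsilon=eps)
            )
            jj, ii = grid.surface_ji[:, 0], grid.surface_ji[:, 1]
            surfaces.append(field.values[jj, ii])
        assert np.all(surfaces[1] <= surfaces[0] + 1e-9)
        assert np.all(surfaces[2] <= surfaces[1] + 1e-9)

    def test_mirror_invariant_field(self, healthy, tumor_props, bc):
        spec = build_domain(50, (10, 10), 3)
        props = {HEALTHY: healthy, TUMOR: tumor_props}
        f1 = solve_steady(build_mesh(spec, 1.0), props, bc)
        f2 = solve_steady(build_mesh(mirror_domain(spec), 1.0), props, bc)
        assert np.nanmax(np.abs(f1.values - f2.values[:, ::-1])) < 1e-10

    def test_nonconvergence_reports_residual(self, healthy, bc):
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        with pytest.raises(ConvergenceError, match="residual"):
            solve_steady(grid, {HEALTHY: healthy}, bc, tol=1e-16, max_iter=1)

    def test_deterministic(self, healthy, bc):
        grid = build_mesh(build_domain(40, (0, 0), 0), 1.0)
        a = solve_steady(grid, {HEALTHY: healthy}, bc)
        b = solve_steady(grid, {HEALTHY: healthy}, bc)
        assert np.array_equal(a.values, b.values, equal_nan=True)


class TestTransient:
    def test_steady_state_is_fixed_point(self, healthy, bc):
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        steady = solve_steady(grid, {HEALTHY: healthy}, bc)
        final, times, _ = solve_transient(
            grid, {HEALTHY: healthy}, bc, steady, dt=100.0, t_end=1000.0
        )
        assert len(times) == 10
        assert np.nanmax(np.abs(final.values - steady.values)) < 1e-6

    def test_equilibrium_stays_constant(self):
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        bc = BoundarySpec(h_f=15.0, epsilon=0.5, T_f=300.0, T_core=300.0)
        final, _, dts = solve_transient(
            grid, {HEALTHY: uniform_props()}, bc, 300.0, dt=50.0, t_end=500.0
        )
        assert np.nanmax(np.abs(final.values - 300.0)) < 1e-8
        assert np.all(dts < 1e-8)

    def test_monotone_approach_to_steady(self, healthy, bc):
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        steady = solve_steady(grid, {HEALTHY: healthy}, bc)
        errs = []
        for t_end in (1e3, 1e4, 1e5):
            final, _, _ = solve_transient(
                grid, {HEALTHY: healthy}, bc, bc.T_f, dt=100.0, t_end=t_end
            )
            errs.append(np.nanmax(np.abs(final.values - steady.values)))
        assert errs[0] > errs[1] > errs[2]

    def test_invalid_stepping_arguments(self, healthy, bc):
        grid = build_mesh(build_domain(40, (0, 0), 0), 2.0)
        with pytest.raises(ValueError):
            solve_transient(grid, {HEALTHY: healthy}, bc, 300.0, dt=-1.0, t_end=10.0)
        with pytest.raises(ValueError):
            solve_transient(grid, {HEALTHY: healthy}, bc, 300.0, dt=10.0, t_end=5.0)


class TestPropsValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(k=-1.0), dict(rho=0.0), dict(omega_b=-1e-4), dict(q_met=-5.0), dict(T_a=-3.0)],
    )
    def test_bad_tissue_props(self, kw):
        base = dict(k=0.48)
        base.update(kw)
        with pytest.raises(ValueError):
            TissueProps(**base)

    @pytest.mark.parametrize(
        "kw", [dict(h_f=-1.0), dict(epsilon=1.5), dict(sigma=0.0), dict(T_f=-2.0)]
    )
    def test_bad_boundary_spec(self, kw):
        with pytest.raises(ValueError):
            BoundarySpec(**kw)
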