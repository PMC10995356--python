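import numpy as np
import pytest

import biogrout as bg
from biogrout.domain import SPECIES, StageSpec, build_grid, initial_state
from biogrout.flow import FlowSolution
from biogrout.solutes import (CFLError, effective_dispersion,
                              reaction_sources, step_solutes, transport_step)


def _flow(grid, params, u):
    return FlowSolution(P=np.full(grid.n_cells, params.P_atm),
                        u=np.full(grid.n_cells + 1, u),
                        rho_l=np.full(grid.n_cells, params.rho_w))


def _stage(kind="retention", flux=0.0, **conc):
    inlet = {s: 0.0 for s in SPECIES}
    inlet.update(conc)
    dirichlet = ("urea", "ca", "nh4") if kind == "inject_cementation" else ()
    return StageSpec(kind=kind, duration=1e9 if kind == "retention" else 1e5,
                     inlet_flux=flux, inlet_conc=inlet,
                     dirichlet_species=dirichlet)


class TestReactionSources:
    def test_zero_rate(self):
        s = reaction_sources(0.0, 0.4)
        assert s.q_urea == 0.0 and s.q_Ca == 0.0 and s.q_NH4 == 0.0

    def test_stoichiometry(self):
        # 1 urea + 1 Ca2+ -> 1 CaCO3 + 2 NH4+, per bulk volume
        s = reaction_sources(1e-2, 0.4)
        assert s.q_urea == pytest.approx(-4e-3)
        assert s.q_Ca == pytest.approx(-4e-3)
        assert s.q_NH4 == pytest.approx(8e-3)

    def test_urea_and_calcium_sinks_equal(self):
        rng = np.random.default_rng(5)
        k = rng.uniform(0.0, 1e-2, 30)
        n = rng.uniform(0.1, 0.4, 30)
        s = reaction_sources(k, n)
        assert np.allclose(s.q_urea, s.q_Ca)
        assert np.allclose(s.q_NH4, -2.0 * s.q_urea)


class TestEffectiveDispersion:
    def test_molecular_only_at_rest(self, params):
        assert effective_dispersion(0.0, params) == pytest.approx(2e-9)

    def test_zero_dispersivity_velocity_independent(self, params):
        assert effective_dispersion(1.0, params) == pytest.approx(params.D_m)

    def test_linear_in_velocity(self, params):
        p = params.replace(alpha_L=1e-3)
        assert effective_dispersion(3.75e-3, p) == pytest.approx(
            1e-3 * 3.75e-3 + 2e-9, rel=1e-9)


class TestTransportStep:
    def test_uniform_field_unchanged_at_rest(self, grid, params):
        C = np.full(grid.n_cells, 123.0)
        D = np.full(grid.n_cells, params.D_m)
        C_new, fluxes = transport_step(
            grid, np.full(grid.n_cells, 0.4), np.zeros(grid.n_cells + 1), C,
            D, 100.0, inlet_conc=0.0, dirichlet_inlet=False)
        assert np.allclose(C_new, 123.0, rtol=1e-14)
        assert fluxes.influx == 0.0 and fluxes.outflux == 0.0

    def test_cfl_violation_rejected(self, grid, params):
        C = np.zeros(grid.n_cells)
        D = np.full(grid.n_cells, params.D_m)
        with pytest.raises(CFLError):
            transport_step(grid, np.full(grid.n_cells, 0.4),
                           np.full(grid.n_cells + 1, 1.5e-3), C, D, 10.0,
                           inlet_conc=0.0, dirichlet_inlet=False)

    def test_advected_front_position(self, params):
        # a step input travels at the pore velocity; after time t the
        # front midpoint sits at v*t within one cell width
        n_cells = 200
        grid = build_grid(0.10, n_cells, 0.05)
        n = np.full(n_cells, params.n_0)
        u = 1.5e-3
        v = u / params.n_0
        C = np.zeros(n_cells)
        D = np.full(n_cells, params.D_m)
        dt = 0.9 * params.n_0 * grid.dx / u
        t_target = 0.05 / v
        steps = int(t_target / dt)
        uu = np.full(n_cells + 1, u)
        for _ in range(steps):
            C, _ = transport_step(grid, n, uu, C, D, dt, inlet_conc=1000.0,
                                  dirichlet_inlet=True)
        front = grid.cell_centers[np.argmin(np.abs(C - 500.0))]
        assert abs(front - v * dt * steps) <= grid.dx + 1e-12

    def test_mass_balance_per_step(self, grid, params):
        # storage change equals boundary fluxes exactly
        rng = np.random.default_rng(2)
        C = rng.uniform(0.0, 1000.0, grid.n_cells)
        n = np.full(grid.n_cells, params.n_0)
        u = np.full(grid.n_cells + 1, 1.0e-3)
        D = np.full(grid.n_cells, params.D_m)
        dt = 0.2
        m0 = np.sum(n * C * grid.dx)
        C_new, fluxes = transport_step(grid, n, u, C, D, dt,
                                       inlet_conc=500.0, dirichlet_inlet=True)
        m1 = np.sum(n * C_new * grid.dx)
        assert m1 - m0 == pytest.approx(fluxes.influx - fluxes.outflux,
                                        rel=1e-12)

    @pytest.mark.parametrize("scheme", ["upwind", "vanleer"])
    def test_positivity_and_boundedness(self, grid, params, scheme):
        # inlet step stays within [0, C0] under admissible dt
        n = np.full(grid.n_cells, params.n_0)
        u = np.full(grid.n_cells + 1, 1.5e-3)
        D = np.full(grid.n_cells, params.D_m)
        dt = 0.9 * params.n_0 * grid.dx / 1.5e-3
        C = np.zeros(grid.n_cells)
        for _ in range(150):
            C, _ = transport_step(grid, n, u, C, D, dt, inlet_conc=1000.0,
                                  dirichlet_inlet=True, scheme=scheme)
        assert np.all(C >= 0.0)
        assert np.all(C <= 1000.0 * (1 + 1e-9))


class TestStepSolutes:
    def test_no_reaction_no_flow_unchanged(self, grid, params):
        state = initial_state(grid, params)
        state.C_urea[:] = 800.0
        state.C_Ca[:] = 800.0
        step_solutes(state, _flow(grid, params, 0.0), 100.0, _stage(), grid,
                     params)
        assert np.allclose(state.C_urea, 800.0, rtol=1e-14)

    def test_equimolar_fields_stay_identical(self, grid, params):
        # urea and Ca2+ share inlet, transport and sink: fields remain equal
        state = initial_state(grid, params)
        stage = _stage("inject_cementation", 1.5e-3, urea=1000.0, ca=1000.0)
        fs = _flow(grid, params, 1.5e-3)
        dt = 0.9 * params.n_0 * grid.dx / 1.5e-3
        for _ in range(100):
            step_solutes(state, fs, dt, stage, grid, params)
        assert np.max(np.abs(state.C_urea - state.C_Ca)) <= \
            1e-10 * max(np.max(state.C_urea), 1.0)

    def test_explicit_sources_applied(self, grid, params):
        state = initial_state(grid, params)
        state.C_urea[:] = 100.0
        state.C_Ca[:] = 100.0
        src = reaction_sources(np.full(grid.n_cells, 1e-3), state.n)
        step_solutes(state, _flow(grid, params, 0.0), 10.0, _stage(), grid,
                     params, sources=src)
        assert np.allclose(state.C_urea, 100.0 - 1e-3 * 10.0)
        assert np.allclose(state.C_NH4, 2e-3 * 10.0)
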