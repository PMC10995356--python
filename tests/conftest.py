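import numpy as np
import pytest
from hypothesis import settings

import biogrout as bg
from biogrout import scheduler, verification

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return bg.default_parameters()


@pytest.fixture(scope="session")
def grid():
    return bg.build_grid()


@pytest.fixture(scope="session")
def default_run():
    """One full single-round simulation, shared across tests."""
    return bg.run("S-7.2-10-1.5")


@pytest.fixture(scope="session")
def suite():
    """The scenario suite (six runs), computed once per session."""
    return verification.scenario_suite()


def ade_breakthrough_error(n_cells=100, peclet=50.0, advection="upwind",
                           pore_volumes=1.5):
    """Relative L2 error of the simulated mid-column breakthrough curve
    against the closed-form step-injection advection-dispersion solution."""
    u = 1.5e-3
    params = bg.default_parameters()
    n0 = params.n_0
    v = u / n0
    L = 0.10
    D = v * L / peclet
    params = params.replace(alpha_L=(D - params.D_m) / v, C0_bact=0.0)
    controls = scheduler.NumericalControls(n_cells=n_cells,
                                           advection_scheme=advection)
    grid = bg.build_grid(L, n_cells, 0.05)
    state = bg.initial_state(grid, params)
    zeros = {s: 0.0 for s in bg.domain.SPECIES}
    stage = bg.StageSpec(kind="inject_cementation",
                         duration=pore_volumes * L * n0 / u, inlet_flux=u,
                         inlet_conc={**zeros, "urea": 1000.0, "ca": 1000.0},
                         dirichlet_species=("urea", "ca", "nh4"),
                         resets_urease_clock=True)
    obs = grid.observation_cell
    times, btc = [], []

    def rec(st):
        times.append(st.t)
        btc.append(st.C_urea[obs])

    scheduler.integrate_stage(state, stage, grid, params, controls, t_c=0.0,
                              record=rec)
    times = np.asarray(times)
    btc = np.asarray(btc)
    analytic = verification.ade_analytic(grid.cell_centers[obs], times, v, D,
                                         1000.0)
    return float(np.linalg.norm(btc - analytic) / np.linalg.norm(analytic))


def batch_equivalence_error(params, C0=1000.0, B=7.2e5, horizon=36000.0):
    """Relative deviation of the zero-flow PDE solver from the stiff-ODE
    batch reference after ``horizon`` seconds."""
    grid = bg.build_grid()
    state = bg.initial_state(grid, params)
    state.C_urea[:] = C0
    state.C_Ca[:] = C0
    state.C_bacs[:] = B
    stage = uniform_retention_stage(horizon)
    scheduler.integrate_stage(state, stage, grid, params,
                              scheduler.NumericalControls(), t_c=0.0)
    _, C_ref = verification.batch_oracle(C0, B, horizon, params, t_c=0.0,
                                         t_eval=[0.0, horizon])
    return float(abs(state.C_urea[grid.observation_cell] - C_ref[-1])
                 / C_ref[-1])


def uniform_retention_stage(duration=36000.0):
    zeros = {s: 0.0 for s in bg.domain.SPECIES}
    return bg.StageSpec(kind="retention", duration=duration,
                        inlet_flux=0.0, inlet_conc=zeros)


@pytest.fixture()
def retention_stage():
    return uniform_retention_stage()
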