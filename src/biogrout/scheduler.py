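"""Stage sequencing and time integration of the coupled column model.

Each grouting round is the stage cycle

    inject_bacteria -> retention (1 h) -> inject_cementation -> retention (10 h)

with rounds concatenated back to back.  Injections deliver a fixed number of
pore volumes (default 1.0) at the scheme's Darcy flux, so the injection
duration is ``PV * L * n_0 / q``.  Within a time step the operators are
applied in sequence: quasi-steady flow, suspended-bacteria transport with
exact attachment/decay, solute transport, and the exact Michaelis-Menten
reaction substep feeding the calcite/porosity/permeability update.  The time
step honours the advective Courant and explicit-diffusion limits and is
truncated exactly at stage boundaries, so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import bacteria, flow, kinetics, medium, solutes
from .domain import (ColumnState, ConfigurationError, Grid1D, GroutingScheme,
                     ModelParameters, SPECIES, StageSpec, build_grid,
                     default_parameters, initial_state, load_scheme)

STAGES_PER_ROUND = 4


@dataclass
class NumericalControls:
    """Discretization and stepping controls."""

    n_cells: int = 100
    length: float = 0.10          # m
    diameter: float = 0.05        # m
    courant: float = 0.9          # fraction of the explicit stability limit
    dt_max: float = 300.0         # s, cap during retention
    advection_scheme: str = "upwind"   # or "vanleer"
    gravity: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.courant <= 1.0:
            raise ValueError("courant must lie in (0, 1]")
        if self.advection_scheme not in ("upwind", "vanleer"):
            raise ValueError(f"unknown advection scheme {self.advection_scheme!r}")


def build_stage_sequence(scheme: GroutingScheme, grid: Grid1D,
                         params: ModelParameters) -> list[StageSpec]:
    """Expand a grouting scheme into its ordered injection/retention stages."""
    if scheme.flow_rate <= 0:
        raise ConfigurationError("scheme flow rate must be positive")
    pore_volume = grid.pore_volume(params.n_0)
    inject_duration = (scheme.injected_pore_volumes * pore_volume
                       / (scheme.flow_rate * grid.area))
    zeros = {s: 0.0 for s in SPECIES}
    stages: list[StageSpec] = []
    for _ in range(scheme.rounds):
        stages.append(StageSpec(
            kind="inject_bacteria", duration=inject_duration,
            inlet_flux=scheme.flow_rate,
            inlet_conc={**zeros, "bacl": scheme.C0_bact},
            dirichlet_species=("bacl",)))
        stages.append(StageSpec(
            kind="retention", duration=scheme.bact_retention,
            inlet_flux=0.0, inlet_conc=dict(zeros)))
        stages.append(StageSpec(
            kind="inject_cementation", duration=inject_duration,
            inlet_flux=scheme.flow_rate,
            inlet_conc={**zeros, "urea": scheme.C0_cem, "ca": scheme.C0_cem},
            dirichlet_species=("urea", "ca", "nh4"),
            resets_urease_clock=True))
        stages.append(StageSpec(
            kind="retention", duration=scheme.cem_retention,
            inlet_flux=0.0, inlet_conc=dict(zeros)))
    return stages


_OBS_FIELDS = ("n", "k", "C_urea", "C_Ca", "C_NH4", "C_bacl", "C_bacs",
               "C_CaCO3")
_PROFILE_FIELDS = _OBS_FIELDS + ("P",)


@dataclass
class SimulationResult:
    """Observation-point series, depth profiles and per-round summaries."""

    scheme: GroutingScheme
    params: ModelParameters
    controls: NumericalControls
    grid: Grid1D
    obs_cell: int
    times: np.ndarray
    obs: dict
    profiles: dict
    round_summaries: list
    audit: dict
    stage_boundaries: np.ndarray

    @property
    def k_reduction_pct(self) -> float:
        return (1.0 - self.obs["k"][-1] / self.params.k_0) * 100.0

    @property
    def n_reduction_pct(self) -> float:
        return (1.0 - self.obs["n"][-1] / self.params.n_0) * 100.0

    def manifest(self) -> dict:
        return {
            "scheme": asdict(self.scheme),
            "parameters": asdict(self.params),
            "controls": asdict(self.controls),
            "grid": {"length": self.grid.length, "n_cells": self.grid.n_cells,
                     "area": self.grid.area},
            "observation_cell": self.obs_cell,
            "end_time_s": float(self.times[-1]),
        }

    def observation_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_s": self.times})
        for name, series in self.obs.items():
            df[name] = series
        return df

    def profile_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_m": self.grid.cell_centers})
        for name, values in self.profiles.items():
            df[name] = values
        return df

    def rounds_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.round_summaries:
            rows.append({"round": s["round"], "t_end_s": s["t_end"],
                         "k_inlet": s["k_profile"][0],
                         "k_obs": s["k_profile"][self.obs_cell],
                         "n_obs": s["n_profile"][self.obs_cell],
                         "calcite_obs": s["calcite_profile"][self.obs_cell],
                         "bacs_obs": s["bacs_profile"][self.obs_cell]})
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        import os
        import yaml
        os.makedirs(outdir, exist_ok=True)
        self.observation_frame().to_csv(
            os.path.join(outdir, "observation_series.csv"), index=False)
        self.profile_frame().to_csv(
            os.path.join(outdir, "final_profiles.csv"), index=False)
        self.rounds_frame().to_csv(
            os.path.join(outdir, "rounds.csv"), index=False)
        with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(self.manifest(), fh, sort_keys=False)


def _round_summary(idx: int, state: ColumnState) -> dict:
    return {"round": idx, "t_end": state.t,
            "k_profile": state.k.copy(), "n_profile": state.n.copy(),
            "calcite_profile": state.C_CaCO3.copy(),
            "bacs_profile": state.C_bacs.copy(),
            "bacl_profile": state.C_bacl.copy()}


def _new_accumulators() -> dict:
    tracked = ("urea", "ca", "nh4", "bacl")
    return {
        "influx": {s: 0.0 for s in tracked},
        "outflux": {s: 0.0 for s in tracked},
        "reacted_mol_per_area": 0.0,   # bulk mol urea hydrolysed, per area
        "expelled": {s: 0.0 for s in ("urea", "ca", "nh4")},
        "bact_decayed": 0.0,
        "bact_expelled": 0.0,
        "max_n_increase": 0.0,
        "min_calcite_increment": 0.0,
        "porosity_floor_hits": 0,
        "steps": 0,
    }


def integrate_stage(state: ColumnState, stage: StageSpec, grid: Grid1D,
                    params: ModelParameters, controls: NumericalControls,
                    t_c: float | None = None, t_end: float | None = None,
                    acc: dict | None = None, record=None) -> dict:
    """Advance the state in place through one injection/retention stage.

    ``t_c`` is the urease-deactivation clock origin (start of the current
    round's cementation injection); ``t_end`` overrides the stage end time
    when stages are chained on an exact cumulative clock.  ``record`` is an
    optional callback invoked after every accepted step.  Returns the audit
    accumulator dict (conserved-quantity bookkeeping per unit area).
    """
    acc = acc if acc is not None else _new_accumulators()
    dx = grid.dx
    t_stage_end = state.t + stage.duration if t_end is None else t_end
    while state.t < t_stage_end * (1.0 - 1e-14) - 1e-12:
        rho = flow.liquid_density(state.C_urea, state.C_Ca, state.C_NH4,
                                  params)
        if stage.is_injection:
            fs = flow.solve_pressure(
                grid, state.k, rho, params,
                top=("flux", stage.inlet_flux),
                bottom=("pressure", params.P_atm),
                gravity=controls.gravity)
        else:
            fs = flow.zero_flow(grid, rho, params)
        state.u = fs.u
        state.P = fs.P

        # time-step selection: combined advection-diffusion explicit
        # stability limit, then truncation at the stage clock
        umax = float(np.max(np.abs(fs.u)))
        v = 0.5 * (np.abs(fs.u[:-1]) + np.abs(fs.u[1:])) / state.n
        D_max = max(float(np.max(solutes.effective_dispersion(v, params))),
                    params.D_bacl)
        rate = (umax / (float(np.min(state.n)) * dx)
                + 3.0 * D_max / dx ** 2)
        dt = controls.dt_max if rate == 0.0 \
            else min(controls.dt_max, controls.courant / rate)
        dt = min(dt, t_stage_end - state.t)

        # bacterial concentration feeding the kinetics, frozen at step start
        B = kinetics.kinetic_bacteria(state, params).copy()
        bact_pre = float(np.sum(state.n * (state.C_bacl + state.C_bacs)) * dx)

        bflux = bacteria.step_suspended_transport(
            state, fs, dt, stage, grid, params,
            courant=controls.courant, scheme=controls.advection_scheme)
        acc["influx"]["bacl"] += bflux["bacl"].influx
        acc["outflux"]["bacl"] += bflux["bacl"].outflux
        # exact decay loss of the total pool over this step
        transported = bflux["bacl"].influx - bflux["bacl"].outflux
        acc["bact_decayed"] += ((bact_pre + transported)
                                * -np.expm1(-params.k_d * dt))

        sflux = solutes.step_solutes(
            state, fs, dt, stage, grid, params, sources=None,
            courant=controls.courant, scheme=controls.advection_scheme)
        for s in ("urea", "ca", "nh4"):
            acc["influx"][s] += sflux[s].influx
            acc["outflux"][s] += sflux[s].outflux

        # exact Michaelis-Menten depletion over the deactivation-weighted
        # step, capped by available Ca2+
        tc_eff = t_c if t_c is not None else state.t
        tau = kinetics.effective_time(state.t, dt, tc_eff, params)
        delta = kinetics.mm_depletion(state.C_urea,
                                      kinetics.max_rate(B, params),
                                      tau, params.k_m)
        delta = np.minimum(delta, state.C_Ca)
        n_before = state.n.copy()
        calcite_before = state.C_CaCO3.copy()
        rx = medium.apply_reaction(state, delta, params)
        acc["reacted_mol_per_area"] += float(
            np.sum(rx["reacted_mol_per_area"]) * dx)
        acc["porosity_floor_hits"] += int(rx["floor_hit"])
        dn = state.n - n_before
        for s in ("urea", "ca", "nh4"):
            acc["expelled"][s] += float(np.sum(-dn * state.species(s)) * dx)
        acc["bact_expelled"] += float(
            np.sum(-dn * (state.C_bacl + state.C_bacs)) * dx)
        acc["max_n_increase"] = max(acc["max_n_increase"], float(np.max(dn)))
        acc["min_calcite_increment"] = min(
            acc["min_calcite_increment"],
            float(np.min(state.C_CaCO3 - calcite_before)))

        state.t += dt
        acc["steps"] += 1
        if record is not None:
            record(state)
    state.t = t_stage_end  # exact stage clock
    return acc


def run(scheme, params: ModelParameters | None = None,
        controls: NumericalControls | None = None) -> SimulationResult:
    """Simulate one grouting scheme on the 1-D column.

    ``scheme`` may be a :class:`GroutingScheme`, a compact code such as
    ``"S-7.2-10-1.5"`` or a path to a YAML scheme file.
    """
    if isinstance(scheme, str):
        scheme = load_scheme(scheme)
    params = params if params is not None else default_parameters()
    controls = controls if controls is not None else NumericalControls()
    grid = build_grid(controls.length, controls.n_cells, controls.diameter)
    stages = build_stage_sequence(scheme, grid, params)
    state = initial_state(grid, params)
    obs = grid.observation_cell
    dx = grid.dx

    times = [0.0]
    series = {name: [getattr(state, name)[obs]] for name in _OBS_FIELDS}
    round_summaries = []
    stage_boundaries = []
    t_c = None

    def record(st: ColumnState) -> None:
        times.append(st.t)
        for name in _OBS_FIELDS:
            series[name].append(getattr(st, name)[obs])

    inventory0 = {s: float(np.sum(state.n * state.species(s)) * dx)
                  for s in ("urea", "ca", "nh4")}
    bact0 = float(np.sum(state.n * (state.C_bacl + state.C_bacs)) * dx)
    acc = _new_accumulators()

    t_stage_end = 0.0
    for i_stage, stage in enumerate(stages):
        if stage.resets_urease_clock:
            t_c = state.t
        t_stage_end += stage.duration
        integrate_stage(state, stage, grid, params, controls,
                        t_c=t_c, t_end=t_stage_end, acc=acc, record=record)
        times[-1] = state.t
        stage_boundaries.append(state.t)
        if (i_stage + 1) % STAGES_PER_ROUND == 0:
            round_summaries.append(
                _round_summary((i_stage + 1) // STAGES_PER_ROUND, state))

    inventory_end = {s: float(np.sum(state.n * state.species(s)) * dx)
                     for s in ("urea", "ca", "nh4")}
    stoich = {"urea": -1.0, "ca": -1.0, "nh4": 2.0}
    reacted = acc["reacted_mol_per_area"]
    balance_residual = {}
    for s in ("urea", "ca", "nh4"):
        expected = (inventory0[s] + acc["influx"][s] - acc["outflux"][s]
                    + stoich[s] * reacted - acc["expelled"][s])
        scale = max(abs(acc["influx"][s]), abs(inventory_end[s]), reacted,
                    1e-30)
        balance_residual[s] = (inventory_end[s] - expected) / scale
    calcite_mol = float(np.sum(state.C_CaCO3 / params.m_CaCO3) * dx)
    calcite_residual = (calcite_mol - reacted) / max(reacted, 1e-30)
    bact_end = float(np.sum(state.n * (state.C_bacl + state.C_bacs)) * dx)
    bact_expected = (bact0 + acc["influx"]["bacl"] - acc["outflux"]["bacl"]
                     - acc["bact_decayed"] - acc["bact_expelled"])
    bact_residual = ((bact_end - bact_expected)
                     / max(bact0, acc["influx"]["bacl"], 1e-30))

    audit = {
        "balance_residual": balance_residual,
        "calcite_ca_residual": calcite_residual,
        "bacteria_residual": bact_residual,
        "influx": acc["influx"], "outflux": acc["outflux"],
        "reacted_mol_per_area": reacted,
        "expelled": acc["expelled"],
        "max_n_increase": acc["max_n_increase"],
        "min_calcite_increment": acc["min_calcite_increment"],
        "porosity_floor_hits": acc["porosity_floor_hits"],
        "steps": acc["steps"],
    }
    return SimulationResult(
        scheme=scheme, params=params, controls=controls, grid=grid,
        obs_cell=obs, times=np.asarray(times),
        obs={k: np.asarray(v) for k, v in series.items()},
        profiles={name: getattr(state, name).copy()
                  for name in _PROFILE_FIELDS},
        round_summaries=round_summaries, audit=audit,
        stage_boundaries=np.asarray(stage_boundaries))


def compare(schemes, params: ModelParameters | None = None,
            controls: NumericalControls | None = None,
            runs: dict | None = None) -> pd.DataFrame:
    """End-of-grouting comparison table across schemes.

    Reductions are relative to the initial state, (x_0 - x_end)/x_0 * 100;
    ratio columns are relative to the first scheme listed.
    """
    if len(schemes) < 2:
        raise ValueError("compare needs at least two schemes")
    rows, codes = [], []
    for scheme in schemes:
        res = scheme if isinstance(scheme, SimulationResult) else None
        if res is None:
            code = scheme if isinstance(scheme, str) else scheme.code
            res = (runs or {}).get(code) or run(scheme, params, controls)
        codes.append(res.scheme.code)
        rows.append({
            "calcite_obs_kg_m3": res.obs["C_CaCO3"][-1],
            "attached_obs": res.obs["C_bacs"][-1],
            "k_obs_m2": res.obs["k"][-1],
            "n_obs": res.obs["n"][-1],
            "k_reduction_pct": res.k_reduction_pct,
            "n_reduction_pct": res.n_reduction_pct,
        })
    df = pd.DataFrame(rows, index=codes)
    ref = df.iloc[0]
    for col in ("calcite_obs_kg_m3", "attached_obs", "k_reduction_pct",
                "n_reduction_pct"):
        with np.errstate(divide="ignore", invalid="ignore"):
            df[col + "_ratio"] = df[col] / ref[col]
    return df
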