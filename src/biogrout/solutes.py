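"""Advection-dispersion-reaction transport of urea, Ca2+ and NH4+.

A conservative finite-volume kernel updates the pore-fluid mass n*C per cell
with first-order upwind advection (an optional van Leer flux limiter sharpens
fronts) and central differencing of the dispersive flux n*D_eff*grad(C).
The same kernel carries the suspended-bacteria field.  Reaction stoichiometry
follows the overall ureolysis reaction: one urea and one Ca2+ consumed, two
NH4+ produced, per mole of urea hydrolysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import Grid1D, ModelParameters, StageSpec


class CFLError(RuntimeError):
    """The requested step exceeds the advective or diffusive stability limit."""


class PositivityError(RuntimeError):
    """A concentration dropped materially below zero after an update."""


@dataclass
class SoluteSources:
    """Bulk-volume reaction source terms (mol/m^3 bulk/s)."""

    q_urea: np.ndarray | float
    q_Ca: np.ndarray | float
    q_NH4: np.ndarray | float


def reaction_sources(k_urea, n) -> SoluteSources:
    """Stoichiometric bulk sources for a pore-volume ureolysis rate."""
    k_urea = np.asarray(k_urea, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k_urea < 0):
        raise ValueError("k_urea must be non-negative")
    q = n * k_urea
    return SoluteSources(q_urea=-q, q_Ca=-q, q_NH4=2.0 * q)


def effective_dispersion(v, params: ModelParameters):
    """Longitudinal dispersion coefficient alpha_L*|v| + D_m (m^2/s)."""
    return params.alpha_L * np.abs(np.asarray(v, dtype=float)) + params.D_m


def _vanleer(r: np.ndarray) -> np.ndarray:
    # van Leer limiter: smooth, TVD
    return (r + np.abs(r)) / (1.0 + np.abs(r))


@dataclass
class TransportFluxes:
    """Boundary bookkeeping of one transport step (per unit area, mol/m^2)."""

    influx: float
    outflux: float


def transport_step(grid: Grid1D, n: np.ndarray, u: np.ndarray, C: np.ndarray,
                   D_cell: np.ndarray, dt: float, *,
                   inlet_conc: float, dirichlet_inlet: bool,
                   courant: float = 0.9, scheme: str = "upwind",
                   positivity_tol: float = 1e-9) -> tuple[np.ndarray, TransportFluxes]:
    """Advance one species by advection + dispersion over ``dt``.

    Works on the conserved pore mass n*C*dx per unit cross-section, so the
    discrete balance  d(storage) = influx - outflux  holds to round-off.
    The inlet face carries the injected concentration advectively; if
    ``dirichlet_inlet`` the inlet value is additionally imposed through a
    half-cell diffusive flux.  The outlet is purely advective (zero diffusive
    flux).  Raises :class:`CFLError` when ``dt`` violates the explicit
    stability limits and :class:`PositivityError` on material undershoot.
    """
    dx = grid.dx
    nc = grid.n_cells
    C = np.asarray(C, dtype=float)

    cr = np.max(np.abs(u)) * dt / (np.min(n) * dx)
    if cr > courant * (1.0 + 1e-12):
        raise CFLError(f"advective Courant number {cr:.3g} exceeds {courant}")
    # combined explicit stability; factor 3 covers the half-cell inlet flux
    dif = 3.0 * np.max(D_cell) * dt / dx ** 2
    if cr + dif > 1.0 + 1e-12:
        raise CFLError(
            f"combined advection-diffusion number {cr + dif:.3g} exceeds 1")
    nD_cell = n * D_cell

    # face dispersive conductances (interior faces)
    nD_face = 0.5 * (nD_cell[:-1] + nD_cell[1:])

    flux = np.zeros(nc + 1)                      # mol m^-2 s^-1, downward > 0
    u_int = u[1:-1]
    up = np.where(u_int >= 0.0, C[:-1], C[1:])
    if scheme == "vanleer" and nc >= 3:
        # piecewise-linear reconstruction of the upwind face value
        dC = np.diff(C)
        cr_face = np.abs(u_int) * dt / (0.5 * (n[:-1] + n[1:]) * dx)
        corr = np.zeros(nc - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_pos = np.where(dC[1:] != 0.0, dC[:-1] / dC[1:], 0.0)
            r_neg = np.where(dC[:-1] != 0.0, dC[1:] / dC[:-1], 0.0)
        corr_pos = 0.5 * _vanleer(r_pos) * (1.0 - cr_face[1:]) * dC[1:]
        corr_neg = -0.5 * _vanleer(r_neg) * (1.0 - cr_face[:-1]) * dC[:-1]
        pos = u_int[1:] >= 0.0
        corr[1:][pos] = corr_pos[pos]
        neg = u_int[:-1] < 0.0
        corr[:-1][neg] = corr_neg[neg]
        up = up + corr
    flux[1:-1] = u_int * up - nD_face * np.diff(C) / dx

    # inlet face: advective carry of the injected fluid ...
    flux[0] = u[0] * (inlet_conc if u[0] >= 0.0 else C[0])
    if dirichlet_inlet:
        # ... plus half-cell diffusive exchange with the imposed value
        flux[0] += -nD_cell[0] * (C[0] - inlet_conc) / (dx / 2.0)
    # outlet face: advective outflow, zero diffusive flux
    flux[-1] = u[-1] * (C[-1] if u[-1] >= 0.0 else 0.0)

    m = n * C * dx
    m_new = m + dt * (flux[:-1] - flux[1:])
    C_new = m_new / (n * dx)

    scale = max(np.max(np.abs(C)), abs(inlet_conc), 1.0)
    if np.min(C_new) < -positivity_tol * scale:
        raise PositivityError(
            f"concentration undershoot {np.min(C_new):.3g} after transport")
    C_new = np.maximum(C_new, 0.0)
    return C_new, TransportFluxes(influx=float(flux[0] * dt),
                                  outflux=float(flux[-1] * dt))


def step_solutes(state, flow, dt: float, stage: StageSpec, grid: Grid1D,
                 params: ModelParameters, sources: SoluteSources | None = None,
                 courant: float = 0.9, scheme: str = "upwind") -> dict:
    """Advance urea, Ca2+ and NH4+ by one transport (+ explicit source) step.

    Returns per-species boundary flux bookkeeping (mol per unit area).
    Reaction handled through an explicit ``sources`` field is applied after
    transport; the scheduler instead couples reaction through the exact
    kinetic substep and passes ``sources=None``.
    """
    v = 0.5 * (np.abs(flow.u[:-1]) + np.abs(flow.u[1:])) / state.n
    D_cell = effective_dispersion(v, params) * np.ones(grid.n_cells)
    audit = {}
    for name, arr in (("urea", state.C_urea), ("ca", state.C_Ca),
                      ("nh4", state.C_NH4)):
        C_new, fluxes = transport_step(
            grid, state.n, flow.u, arr, D_cell, dt,
            inlet_conc=stage.inlet_conc[name],
            dirichlet_inlet=name in stage.dirichlet_species,
            courant=courant, scheme=scheme)
        arr[:] = C_new
        audit[name] = fluxes
    if sources is not None:
        state.C_urea += np.asarray(sources.q_urea) / state.n * dt
        state.C_Ca += np.asarray(sources.q_Ca) / state.n * dt
        state.C_NH4 += np.asarray(sources.q_NH4) / state.n * dt
        for arr in (state.C_urea, state.C_Ca, state.C_NH4):
            if np.min(arr) < -1e-12 * max(1.0, float(np.max(np.abs(arr)))):
                raise PositivityError("source application drove a species negative")
            np.maximum(arr, 0.0, out=arr)
    return audit
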