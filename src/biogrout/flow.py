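"""Darcy flow on the evolving permeability field.

Flow is quasi-steady: at each time step the incompressible continuity
equation is re-solved on the current permeability and liquid-density fields,
giving cell pressures and face Darcy fluxes.  Retention stages are treated as
static reaction periods with zero flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import ConfigurationError, Grid1D, ModelParameters

# liquid-density increments per unit concentration (kg/m^3 per mol/m^3)
DENSITY_COEFF_UREA = 0.0154994
DENSITY_COEFF_CA = 0.0867338
DENSITY_COEFF_NH4 = 0.0158991


@dataclass
class FlowSolution:
    """Pressure, face Darcy flux and liquid density of one flow solve."""

    P: np.ndarray        # Pa, per cell
    u: np.ndarray        # m/s, per face, positive downward
    rho_l: np.ndarray    # kg/m^3, per cell


def liquid_density(C_urea, C_Ca, C_NH4, params: ModelParameters):
    """Solution density as a linear function of solute concentrations."""
    C_urea = np.asarray(C_urea, dtype=float)
    C_Ca = np.asarray(C_Ca, dtype=float)
    C_NH4 = np.asarray(C_NH4, dtype=float)
    if np.any(C_urea < 0) or np.any(C_Ca < 0) or np.any(C_NH4 < 0):
        raise ValueError("concentrations must be non-negative")
    rho = (params.rho_w + DENSITY_COEFF_UREA * C_urea
           + DENSITY_COEFF_CA * C_Ca + DENSITY_COEFF_NH4 * C_NH4)
    return float(rho) if rho.ndim == 0 else rho


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def solve_pressure(grid: Grid1D, k: np.ndarray, rho_l: np.ndarray,
                   params: ModelParameters, *,
                   top: tuple[str, float], bottom: tuple[str, float],
                   gravity: bool = True) -> FlowSolution:
    """Solve steady incompressible Darcy flow on the column.

    ``top``/``bottom`` are ``("flux", q)`` (prescribed Darcy flux, positive
    into the column at the top) or ``("pressure", P)`` boundary conditions.
    Face permeabilities are harmonic means; the gravity term uses the
    arithmetic face-mean density.  With z increasing downward the flux law is
    u = -(k/mu) (dP/dz - rho g).
    """
    k = np.asarray(k, dtype=float)
    rho_l = np.asarray(rho_l, dtype=float)
    if np.any(k <= 0):
        raise ValueError("permeability must be strictly positive")
    if top[0] == "flux" and bottom[0] == "flux":
        raise ConfigurationError(
            "all-flux boundaries leave the pressure level undetermined")
    nc = grid.n_cells
    dx = grid.dx
    g = params.g if gravity else 0.0
    mu = params.mu

    k_face = _harmonic(k[:-1], k[1:])                 # interior faces
    rho_face = 0.5 * (rho_l[:-1] + rho_l[1:])
    T_int = k_face / (mu * dx)                        # interior transmissibility

    main = np.zeros(nc)
    lower = np.zeros(nc - 1)
    upper = np.zeros(nc - 1)
    b = np.zeros(nc)

    # interior faces contribute to both adjacent cell balances
    main[:-1] += T_int
    main[1:] += T_int
    lower[:] = -T_int
    upper[:] = -T_int
    grav_int = (k_face / mu) * rho_face * g
    b[:-1] -= grav_int
    b[1:] += grav_int

    # top boundary (face 0, belongs to cell 0)
    if top[0] == "flux":
        b[0] += top[1]
    elif top[0] == "pressure":
        T_top = k[0] / (mu * dx / 2.0)
        main[0] += T_top
        b[0] += T_top * top[1] + (k[0] / mu) * rho_l[0] * g
    else:
        raise ConfigurationError(f"unknown top boundary kind {top[0]!r}")

    # bottom boundary (face nc, belongs to cell nc-1)
    if bottom[0] == "pressure":
        T_bot = k[-1] / (mu * dx / 2.0)
        main[-1] += T_bot
        b[-1] += T_bot * bottom[1] - (k[-1] / mu) * rho_l[-1] * g
    elif bottom[0] == "flux":
        b[-1] -= bottom[1]
    else:
        raise ConfigurationError(f"unknown bottom boundary kind {bottom[0]!r}")

    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    P = spla.spsolve(A, b)

    u = np.empty(nc + 1)
    u[1:-1] = -(k_face / mu) * ((P[1:] - P[:-1]) / dx - rho_face * g)
    if top[0] == "flux":
        u[0] = top[1]
    else:
        u[0] = -(k[0] / mu) * ((P[0] - top[1]) / (dx / 2.0) - rho_l[0] * g)
    if bottom[0] == "pressure":
        u[-1] = -(k[-1] / mu) * ((bottom[1] - P[-1]) / (dx / 2.0)
                                 - rho_l[-1] * g)
    else:
        u[-1] = bottom[1]
    return FlowSolution(P=P, u=u, rho_l=rho_l)


def zero_flow(grid: Grid1D, rho_l: np.ndarray,
              params: ModelParameters) -> FlowSolution:
    """Static retention-period flow field: u = 0, hydrostatic pressure."""
    rho_l = np.asarray(rho_l, dtype=float)
    P = params.P_atm + np.cumsum(rho_l * params.g * grid.dx) \
        - 0.5 * rho_l * params.g * grid.dx
    return FlowSolution(P=P, u=np.zeros(grid.n_cells + 1), rho_l=rho_l)
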