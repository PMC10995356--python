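"""Calcite accumulation and the porosity/permeability response.

Precipitated calcite is immobile: it accumulates on grain surfaces, consumes
pore space in proportion to its mass, and permeability follows the porosity
through the Kozeny-Carman relation k = d_m^2/180 * n^3/(1-n)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: porosity floor keeping Kozeny-Carman finite in fully clogged cells
N_MIN = 0.01


def kozeny_carman(n, d_m_grain):
    """Permeability (m^2) from porosity and mean grain diameter."""
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0.0) or np.any(n >= 1.0):
        raise ValueError("porosity must lie strictly in (0, 1)")
    k = d_m_grain ** 2 / 180.0 * n ** 3 / (1.0 - n) ** 2
    return float(k) if k.ndim == 0 else k


def derive_grain_size(k0: float, n0: float) -> float:
    """Mean grain diameter (m) that reproduces k0 at porosity n0.

    Closed-form inversion of Kozeny-Carman: d_m = sqrt(180 k0 (1-n0)^2/n0^3).
    """
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if not 0.0 < n0 < 1.0:
        raise ValueError("n0 must lie in (0, 1)")
    return math.sqrt(180.0 * k0 * (1.0 - n0) ** 2 / n0 ** 3)


@dataclass
class MediumUpdate:
    """Per-cell increments of one precipitation step."""

    dC_CaCO3: np.ndarray   # calcite mass gain, kg/m^3 bulk (>= 0)
    dn: np.ndarray         # porosity change (<= 0)
    k_new: np.ndarray      # updated permeability, m^2
    floor_hit: bool = False


def precipitate(k_urea, n, dt: float, params, C_urea=None, C_Ca=None,
                d_m_grain: float | None = None) -> MediumUpdate:
    """Convert a ureolysis rate sustained over ``dt`` into medium changes.

    ``k_urea`` is per pore volume, so the bulk calcite production rate is
    m_CaCO3 * n * k_urea.  The step is capped by the reactant actually
    available (min of urea and Ca2+ in the cell) and by the porosity floor.
    """
    k_urea = np.atleast_1d(np.asarray(k_urea, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(k_urea < 0) or dt < 0:
        raise ValueError("k_urea and dt must be non-negative")
    moles = k_urea * dt                     # mol per m^3 pore fluid
    if C_urea is not None:
        moles = np.minimum(moles, np.maximum(np.asarray(C_urea, float), 0.0))
    if C_Ca is not None:
        moles = np.minimum(moles, np.maximum(np.asarray(C_Ca, float), 0.0))
    dC = params.m_CaCO3 * n * moles         # kg/m^3 bulk
    dn = -dC / params.rho_CaCO3
    floor_hit = bool(np.any(n + dn < N_MIN))
    if floor_hit:
        dn = np.maximum(dn, N_MIN - n)
        dC = -dn * params.rho_CaCO3
    d_m = params.d_m_grain if d_m_grain is None else d_m_grain
    k_new = kozeny_carman(n + dn, d_m)
    return MediumUpdate(dC_CaCO3=dC, dn=dn, k_new=np.atleast_1d(k_new),
                        floor_hit=floor_hit)


def apply_reaction(state, delta_mol: np.ndarray, params) -> dict:
    """Apply a reacted-urea field (mol per m^3 pore fluid) to the state.

    Consumes urea and Ca2+ stoichiometrically, releases 2 NH4+, accrues
    calcite, shrinks porosity and updates permeability.  ``delta_mol`` must
    already be capped by reactant availability.  Returns audit increments in
    bulk moles per unit column cross-section.
    """
    delta = np.asarray(delta_mol, dtype=float)
    n_old = state.n.copy()
    dC = params.m_CaCO3 * n_old * delta
    dn = -dC / params.rho_CaCO3
    floor_hit = bool(np.any(n_old + dn < N_MIN))
    if floor_hit:
        dn = np.maximum(dn, N_MIN - n_old)
        dC = -dn * params.rho_CaCO3
        delta = dC / (params.m_CaCO3 * n_old)
    state.C_urea -= delta
    state.C_Ca -= delta
    state.C_NH4 += 2.0 * delta
    state.C_CaCO3 += dC
    state.n = n_old + dn
    state.k = kozeny_carman(state.n, params.d_m_grain)
    return {"reacted_mol_per_area": n_old * delta,  # x dx x area = bulk moles
            "floor_hit": floor_hit}
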