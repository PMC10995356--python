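"""Kinetically controlled ureolysis.

The overall urea-hydrolysis rate is Michaelis-Menten in urea, proportional to
the bacterial concentration, and damped by an exponential loss of urease
activity whose clock starts when the cementation solution of the current
round is injected:

    k_urea = u_sp * C_bact * C_urea / (k_m + C_urea) * f_d(t),
    f_d(t) = exp(-(t - t_c) / t_d).

An alternative deactivation form exp(-k_d (t - t_c)) is selectable through
``ModelParameters.urease_decay_mode``.

Because the rate law is separable, the depletion of urea in a closed cell
over a finite step has a closed form via the Lambert W function; the solver
uses that instead of an explicit Euler update, which makes the reaction
substep exact for frozen bacterial fields and removes any kinetic time-step
restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .domain import ModelParameters


@dataclass
class UreolysisRate:
    """Volumetric hydrolysis rate and its factors."""

    k_urea: np.ndarray | float   # mol/m^3 pore fluid / s
    U_max: np.ndarray | float    # mol/m^3/s
    f_d: float                   # deactivation factor in (0, 1]


def max_rate(C_bact, params: ModelParameters):
    """Maximum hydrolysis rate U_max = u_sp * C_bact (mol/m^3/s)."""
    return params.u_sp * np.asarray(C_bact, dtype=float)


def _decay_rate(params: ModelParameters) -> float:
    if params.urease_decay_mode == "time_constant":
        return 1.0 / params.t_d
    return params.k_d


def deactivation(t: float, t_c: float, params: ModelParameters) -> float:
    """Urease activity remaining at time ``t``, clock origin ``t_c``."""
    if t < t_c:
        raise ValueError("t must not precede the cementation clock origin t_c")
    return float(np.exp(-_decay_rate(params) * (t - t_c)))


def ureolysis_rate(C_urea, C_bact, t: float, t_c: float,
                   params: ModelParameters) -> UreolysisRate:
    """Instantaneous ureolysis rate for given urea and bacteria fields."""
    C_urea = np.asarray(C_urea, dtype=float)
    if np.any(C_urea < 0) or np.any(np.asarray(C_bact) < 0):
        raise ValueError("concentrations must be non-negative")
    U = max_rate(C_bact, params)
    f = deactivation(t, t_c, params)
    k = U * C_urea / (params.k_m + C_urea) * f
    if np.ndim(k) == 0:
        return UreolysisRate(k_urea=float(k), U_max=float(U), f_d=f)
    return UreolysisRate(k_urea=k, U_max=U, f_d=f)


def kinetic_bacteria(state, params: ModelParameters) -> np.ndarray:
    """Bacterial concentration entering the rate law (total or attached)."""
    if params.kinetics_bacteria == "attached":
        return state.C_bacs
    return state.C_bacl + state.C_bacs


def effective_time(t: float, dt: float, t_c: float, params: ModelParameters,
                   bacterial_decay: bool = True) -> float:
    """Deactivation-weighted duration of the step [t, t+dt].

    tau = integral over the step of f_d(s) * exp(-k_d (s - t)) ds, so that
    U_max(t) * tau is the urea a saturated cell would hydrolyse during the
    step while urease deactivates and the bacterial pool decays.
    """
    a = _decay_rate(params) + (params.k_d if bacterial_decay else 0.0)
    f0 = deactivation(t, t_c, params)
    if a == 0.0:
        return f0 * dt
    return f0 * (1.0 - np.exp(-a * dt)) / a


def mm_depletion(C0, U_max, tau, k_m: float):
    """Urea consumed in a closed cell over an effective duration ``tau``.

    Integrates dC/dtau = -U_max C/(k_m + C) exactly: the implicit solution
    k_m ln(C0/C) + (C0 - C) = U_max tau inverts through the principal branch
    of the Lambert W function.  Returns the consumed amount C0 - C(tau) >= 0,
    never exceeding C0.
    """
    C0, depleted = np.broadcast_arrays(
        np.asarray(C0, dtype=float),
        np.asarray(U_max, dtype=float) * np.asarray(tau, dtype=float))
    scalar = C0.ndim == 0
    C0 = np.atleast_1d(np.ascontiguousarray(C0))
    depleted = np.atleast_1d(np.ascontiguousarray(depleted))
    out = np.zeros(C0.shape)
    active = (depleted > 0.0) & (C0 > 0.0)
    if np.any(active):
        with np.errstate(over="ignore"):
            arg = C0[active] / k_m * np.exp((C0[active] - depleted[active])
                                            / k_m)
        C = k_m * np.real(lambertw(arg))
        big = ~np.isfinite(arg)
        if np.any(big):
            # the exponential overflowed (C0 >> k_m, mild depletion): solve
            # the implicit relation by Newton instead, seeded at C0 - U tau
            C0b = C0[active][big]
            db = depleted[active][big]
            x = np.maximum(C0b - db, 0.5 * C0b)
            for _ in range(8):
                f = k_m * np.log(C0b / x) + (C0b - x) - db
                x = np.clip(x + f / (k_m / x + 1.0), 1e-12 * C0b, C0b)
            C = np.asarray(C, dtype=float)
            C[big] = x
        out[active] = C0[active] - np.clip(C, 0.0, C0[active])
    return float(out[0]) if scalar else out
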