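"""Independent oracles and benchmark audits gating the column solver.

Three layers: (i) a high-accuracy batch-kinetics ODE reference for the
zero-flow limit, (ii) the closed-form step-injection advection-dispersion
solution for the reaction-free transport limit, and (iii) machine-readable
mass-balance audits plus the scenario suite that recomputes the
between-scheme ratios and reductions of the simulation campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import erfc

from . import kinetics, scheduler
from .domain import ModelParameters, default_parameters


# ---------------------------------------------------------------------------
# batch-kinetics oracle
# ---------------------------------------------------------------------------

def batch_oracle(C0_urea: float, C_bact: float, horizon: float,
                 params: ModelParameters, t_c: float = 0.0,
                 t_eval=None, rtol: float = 1e-10,
                 bacterial_decay: bool = True):
    """Reference urea trajectory in a closed, well-mixed cell.

    Integrates dC/dt = -u_sp B(t) C/(k_m + C) f_d(t) with a stiff ODE solver
    at tight tolerance; B(t) = C_bact e^{-k_d t} when ``bacterial_decay``.
    Returns (t, C) arrays.  Serves as ground truth for the PDE solver's
    zero-flow limit.
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 201)
    if C0_urea == 0.0 or C_bact == 0.0:
        return np.asarray(t_eval), np.zeros(len(t_eval))

    def rhs(t, y):
        C = max(y[0], 0.0)
        f_d = kinetics.deactivation(max(t, t_c), t_c, params)
        B = C_bact * (np.exp(-params.k_d * t) if bacterial_decay else 1.0)
        return [-params.u_sp * B * C / (params.k_m + C) * f_d]

    sol = solve_ivp(rhs, (0.0, horizon), [C0_urea], method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=1e-12 * max(C0_urea, 1.0))
    if not sol.success:
        raise RuntimeError(f"batch oracle integration failed: {sol.message}")
    return sol.t, np.maximum(sol.y[0], 0.0)


# ---------------------------------------------------------------------------
# advection-dispersion oracle
# ---------------------------------------------------------------------------

def ade_analytic(x, t, v: float, D: float, C0: float):
    """Step-injection solution of the 1-D advection-dispersion equation.

    Semi-infinite domain, resident concentration initially zero, inlet held
    at C0 from t = 0 (Ogata-Banks error-function form):

        C/C0 = 1/2 [erfc((x - v t)/(2 sqrt(D t)))
                    + exp(v x / D) erfc((x + v t)/(2 sqrt(D t)))]
    """
    xx, tt = np.broadcast_arrays(np.asarray(x, dtype=float),
                                 np.asarray(t, dtype=float))
    scalar = xx.ndim == 0
    xx = np.atleast_1d(xx)
    tt = np.atleast_1d(tt)
    out = np.zeros(xx.shape)
    pos = tt > 0
    s = 2.0 * np.sqrt(D * tt[pos])
    with np.errstate(over="ignore"):
        tail = np.exp(np.minimum(v * xx[pos] / D, 700.0)) \
            * erfc((xx[pos] + v * tt[pos]) / s)
    out[pos] = 0.5 * C0 * (erfc((xx[pos] - v * tt[pos]) / s) + tail)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# audits
# ---------------------------------------------------------------------------

@dataclass
class Check:
    name: str
    value: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.value) <= self.tolerance


@dataclass
class AuditReport:
    """Machine-readable pass/fail report of the conservation audits."""

    checks: list = field(default_factory=list)

    def add(self, name: str, value: float, tolerance: float) -> None:
        self.checks.append(Check(name, float(value), tolerance))

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {c.name: {"value": c.value, "tolerance": c.tolerance,
                         "passed": c.passed} for c in self.checks}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"check": c.name, "value": c.value,
                              "tolerance": c.tolerance, "passed": c.passed}
                             for c in self.checks])


MASS_BALANCE_TOL = 1e-6
CALCITE_MOLE_TOL = 1e-6
BACTERIA_DECAY_TOL = 1e-3


def audit_result(result: scheduler.SimulationResult) -> AuditReport:
    """Wrap a run's conservation accumulators into an AuditReport."""
    report = AuditReport()
    for s, residual in result.audit["balance_residual"].items():
        report.add(f"mass_balance_{s}", residual, MASS_BALANCE_TOL)
    report.add("calcite_ca_mole_match", result.audit["calcite_ca_residual"],
               CALCITE_MOLE_TOL)
    report.add("bacteria_inventory", result.audit["bacteria_residual"],
               BACTERIA_DECAY_TOL)
    report.add("porosity_monotone_decrease", result.audit["max_n_increase"],
               0.0)
    report.add("calcite_monotone_increase",
               result.audit["min_calcite_increment"], 0.0)
    return report


# ---------------------------------------------------------------------------
# scenario suite
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSuite:
    """Computed between-scheme metrics of the simulation campaign."""

    metrics: dict
    table: pd.DataFrame
    audit: AuditReport
    runs: dict


def _end_obs(result: scheduler.SimulationResult, name: str) -> float:
    return float(result.obs[name][-1])


def scenario_suite(params: ModelParameters | None = None,
                   controls: scheduler.NumericalControls | None = None,
                   runs: dict | None = None) -> ScenarioSuite:
    """Run the scheme pairs behind every campaign metric and collect results.

    Metrics are evaluated at the mid-column observation point at the end of
    grouting (end of the final retention stage), except the multi-round
    permeability metrics, which probe the inlet-most (grouting hole) cell at
    round boundaries.
    """
    params = params if params is not None else default_parameters()
    controls = controls if controls is not None \
        else scheduler.NumericalControls()
    runs = dict(runs) if runs else {}

    def get(code: str) -> scheduler.SimulationResult:
        if code not in runs:
            runs[code] = scheduler.run(code, params, controls)
        return runs[code]

    low = get("S-4.3-10-1.5")
    high = get("S-7.2-10-1.5")
    rate10 = get("S-7.2-10-1.0")
    rate20 = get("S-7.2-10-2.0")
    multi_high = get("M-7.2-10-1.5")
    multi_low = get("M-4.3-10-1.5")

    k_inlet_round = [s["k_profile"][0] for s in multi_high.round_summaries]
    k_inlet_low_round = [s["k_profile"][0] for s in multi_low.round_summaries]

    metrics = {
        "calcite_ratio_high_vs_low_bacteria":
            _end_obs(high, "C_CaCO3") / _end_obs(low, "C_CaCO3"),
        "perm_reduction_pct_low_bacteria": low.k_reduction_pct,
        "porosity_reduction_pct_low_bacteria": low.n_reduction_pct,
        "perm_reduction_pct_high_bacteria": high.k_reduction_pct,
        "perm_reduction_ratio_high_vs_low_bacteria":
            high.k_reduction_pct / low.k_reduction_pct,
        "attached_ratio_rate_1p5_vs_1p0":
            _end_obs(high, "C_bacs") / _end_obs(rate10, "C_bacs"),
        "attached_ratio_rate_2p0_vs_1p0":
            _end_obs(rate20, "C_bacs") / _end_obs(rate10, "C_bacs"),
        "calcite_ratio_rate_1p5_vs_1p0":
            _end_obs(high, "C_CaCO3") / _end_obs(rate10, "C_CaCO3"),
        "perm_reduction_pct_rate_1p0": rate10.k_reduction_pct,
        "perm_reduction_pct_rate_2p0": rate20.k_reduction_pct,
        "inlet_perm_fold_round1_vs_round5":
            k_inlet_round[0] / k_inlet_round[4],
        "perm_pct_diff_high4_vs_low5":
            (k_inlet_low_round[4] - k_inlet_round[3])
            / k_inlet_low_round[4] * 100.0,
    }
    table = scheduler.compare(
        ["S-4.3-10-1.5", "S-7.2-10-1.5", "S-7.2-10-1.0", "S-7.2-10-2.0",
         "M-7.2-10-1.5", "M-4.3-10-1.5"],
        params, controls, runs=runs)
    return ScenarioSuite(metrics=metrics, table=table,
                         audit=audit_result(high), runs=runs)
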