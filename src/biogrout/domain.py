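"""Shared domain types for the MICP column simulator.

Holds the physical parameter set, the 1-D column grid, the evolving column
state, and the grouting-scheme registry with its compact scheme-code parser.

Units are SI throughout except bacterial concentrations, which are carried in
cells/mL as an opaque concentration scale: the maximum urease constant
``u_sp`` is interpreted per unit of bacterial concentration on that same
scale, so ``U_max = u_sp * C_bact`` is a volumetric rate in mol/m^3/s.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, fields, replace

import numpy as np
import yaml

GRAVITY = 9.81            # m/s^2
ATMOSPHERIC_PRESSURE = 101325.0  # Pa

#: aqueous species tracked on the column
SPECIES = ("urea", "ca", "nh4", "bacl")


class SchemeParseError(ValueError):
    """A grouting-scheme code or config file could not be interpreted."""


class ConfigurationError(ValueError):
    """Inconsistent boundary-condition or solver configuration."""


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the bio-chemo-hydro model.

    Defaults are the calibrated sand-column values used throughout the
    simulator.  ``d_m_grain`` is derived from ``k_0`` and ``n_0`` through the
    Kozeny-Carman relation when not given explicitly, so the initial
    permeability is reproduced exactly by the porosity-permeability law.
    """

    rho_w: float = 1000.0        # water density, kg/m^3
    mu: float = 1e-3             # dynamic viscosity, Pa s
    k_m: float = 55.0            # Michaelis half-saturation constant, mol/m^3
    m_urea: float = 0.078        # molar mass of urea, kg/mol
    m_Ca: float = 0.04           # molar mass of Ca2+, kg/mol
    m_NH4: float = 0.018         # molar mass of NH4+, kg/mol
    m_CaCO3: float = 0.1         # molar mass of CaCO3, kg/mol
    rho_CaCO3: float = 2710.0    # calcite density, kg/m^3
    D_m: float = 2e-9            # molecular diffusion coefficient, m^2/s
    u_sp: float = 1.4e-8         # max urease constant, (mol/m^3/s)/(cells/mL)
    t_d: float = 288000.0        # urease-deactivation time constant, s
    k_att: float = 1.52e-3       # bacterial attachment rate, 1/s
    k_d: float = 3.18e-7         # bacterial decay rate, 1/s
    k_0: float = 2e-12           # initial permeability, m^2
    n_0: float = 0.40            # initial porosity
    C0_bact: float = 7.2e5       # reference injected bacterial conc., cells/mL
    alpha_L: float = 0.0         # longitudinal dispersivity, m
    alpha_T: float = 0.0         # transverse dispersivity, m (unused in 1-D)
    g: float = GRAVITY           # gravitational acceleration, m/s^2
    P_atm: float = ATMOSPHERIC_PRESSURE  # reference pressure, Pa
    d_m_grain: float | None = None       # mean grain diameter, m
    D_bacl: float | None = None          # bacterial diffusion coeff., m^2/s
    # model options
    urease_decay_mode: str = "time_constant"   # or "decay_rate"
    kinetics_bacteria: str = "total"           # or "attached"

    def __post_init__(self) -> None:
        from .medium import derive_grain_size, kozeny_carman

        for name in ("rho_w", "mu", "k_m", "m_urea", "m_Ca", "m_NH4",
                     "m_CaCO3", "rho_CaCO3", "D_m", "u_sp", "t_d",
                     "k_att", "k_d", "k_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if not 0.0 < self.n_0 < 1.0:
            raise ValueError("n_0 must lie in (0, 1)")
        if self.urease_decay_mode not in ("time_constant", "decay_rate"):
            raise ValueError(f"unknown urease_decay_mode {self.urease_decay_mode!r}")
        if self.kinetics_bacteria not in ("total", "attached"):
            raise ValueError(f"unknown kinetics_bacteria {self.kinetics_bacteria!r}")
        if self.d_m_grain is None:
            object.__setattr__(self, "d_m_grain",
                               derive_grain_size(self.k_0, self.n_0))
        if self.d_m_grain <= 0:
            raise ValueError("d_m_grain must be strictly positive")
        if not math.isclose(kozeny_carman(self.n_0, self.d_m_grain),
                            self.k_0, rel_tol=1e-10):
            raise ValueError(
                "d_m_grain inconsistent with k_0 and n_0 under Kozeny-Carman")
        if self.D_bacl is None:
            object.__setattr__(self, "D_bacl", self.D_m)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        if ("k_0" in changes or "n_0" in changes) and "d_m_grain" not in changes:
            changes.setdefault("d_m_grain", None)
        return replace(self, **changes)


def default_parameters() -> ModelParameters:
    """The default parameter set of the model."""
    return ModelParameters()


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D finite-volume grid of the sand column.

    The coordinate ``z`` increases downward: the grouting inlet is the face at
    z = 0 and the outlet the face at z = length.
    """

    length: float
    n_cells: int
    area: float
    face_positions: np.ndarray
    cell_centers: np.ndarray

    @property
    def dx(self) -> float:
        return self.length / self.n_cells

    @property
    def cell_volumes(self) -> np.ndarray:
        return np.full(self.n_cells, self.area * self.dx)

    def pore_volume(self, porosity: float | np.ndarray) -> float:
        """Total pore volume (m^3) for a uniform or per-cell porosity."""
        return float(np.sum(self.cell_volumes * porosity))

    @property
    def observation_cell(self) -> int:
        """Index of the cell containing the column mid-height."""
        return int(np.searchsorted(self.face_positions, self.length / 2.0,
                                   side="right") - 1)


def build_grid(length: float = 0.10, n_cells: int = 100,
               diameter: float = 0.05) -> Grid1D:
    """Build a uniform column grid (default: 10 cm tall, 5 cm diameter)."""
    if length <= 0 or diameter <= 0:
        raise ValueError("column length and diameter must be positive")
    if n_cells < 3:
        raise ValueError("n_cells must be at least 3")
    faces = np.linspace(0.0, length, n_cells + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    area = math.pi * (diameter / 2.0) ** 2
    return Grid1D(length=length, n_cells=n_cells, area=area,
                  face_positions=faces, cell_centers=centers)


# ---------------------------------------------------------------------------
# evolving state
# ---------------------------------------------------------------------------

@dataclass
class ColumnState:
    """All evolving fields on the column grid.

    Aqueous concentrations are per m^3 of pore fluid; attached bacteria are
    immobile and carried on the same numeric scale as the suspended pool;
    calcite is a bulk-volume mass concentration (kg per m^3 of column).
    """

    t: float
    P: np.ndarray        # cell pressures, Pa
    u: np.ndarray        # face Darcy fluxes, m/s (positive downward)
    n: np.ndarray        # porosity
    k: np.ndarray        # permeability, m^2
    C_urea: np.ndarray   # mol/m^3 pore fluid
    C_Ca: np.ndarray     # mol/m^3 pore fluid
    C_NH4: np.ndarray    # mol/m^3 pore fluid
    C_bacl: np.ndarray   # suspended bacteria, cells/mL
    C_bacs: np.ndarray   # attached bacteria, cells/mL
    C_CaCO3: np.ndarray  # precipitated calcite, kg/m^3 bulk

    def copy(self) -> "ColumnState":
        return ColumnState(
            t=self.t, **{f.name: getattr(self, f.name).copy()
                         for f in fields(self) if f.name != "t"})

    def species(self, name: str) -> np.ndarray:
        return {"urea": self.C_urea, "ca": self.C_Ca,
                "nh4": self.C_NH4, "bacl": self.C_bacl}[name]


def initial_state(grid: Grid1D, params: ModelParameters) -> ColumnState:
    """Pristine water-saturated column at hydrostatic pressure."""
    nc = grid.n_cells
    z = grid.cell_centers
    return ColumnState(
        t=0.0,
        P=params.P_atm + params.rho_w * params.g * z,
        u=np.zeros(nc + 1),
        n=np.full(nc, params.n_0),
        k=np.full(nc, params.k_0),
        C_urea=np.zeros(nc),
        C_Ca=np.zeros(nc),
        C_NH4=np.zeros(nc),
        C_bacl=np.zeros(nc),
        C_bacs=np.zeros(nc),
        C_CaCO3=np.zeros(nc),
    )


# ---------------------------------------------------------------------------
# grouting schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroutingScheme:
    """One staged-injection treatment recipe.

    ``code`` follows the ``{S|M}-{bact}-{cem}-{rate}`` convention: S = single
    round, M = five rounds; bacterial concentration in 1e5 cells/mL;
    cementation (equimolar urea + Ca2+) concentration in 100 mol/m^3; inlet
    Darcy flux in 1e-3 m/s.  Example: ``S-7.2-10-1.5``.
    """

    code: str
    C0_bact: float               # cells/mL
    bact_retention: float        # s
    flow_rate: float             # inlet Darcy flux, m/s
    C0_cem: float                # mol/m^3 (urea and Ca2+ each)
    cem_retention: float         # s
    rounds: int
    injected_pore_volumes: float = 1.0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if min(self.C0_bact, self.C0_cem) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.injected_pore_volumes <= 0:
            raise ValueError("injected_pore_volumes must be positive")


_CODE_RE = re.compile(r"^(?P<prefix>[A-Za-z]+)-(?P<bact>[^-]+)-(?P<cem>[^-]+)"
                      r"-(?P<rate>[^-]+)$")

BACT_RETENTION = 3600.0    # s, rest after the bacterial injection
CEM_RETENTION = 36000.0    # s, rest after the cementation injection


def parse_scheme(code: str, injected_pore_volumes: float = 1.0) -> GroutingScheme:
    """Parse a compact scheme code into a :class:`GroutingScheme`."""
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise SchemeParseError(
            f"scheme code {code!r} does not match '{{S|M}}-bact-cem-rate'")
    prefix = m.group("prefix").upper()
    if prefix not in ("S", "M"):
        raise SchemeParseError(
            f"scheme code {code!r}: unknown prefix {m.group('prefix')!r} "
            "(expected 'S' for single-round or 'M' for multi-round)")
    values = {}
    for part in ("bact", "cem", "rate"):
        try:
            values[part] = float(m.group(part))
        except ValueError:
            raise SchemeParseError(
                f"scheme code {code!r}: field {part!r} is not numeric") from None
        if values[part] <= 0:
            raise SchemeParseError(
                f"scheme code {code!r}: field {part!r} must be positive")
    return GroutingScheme(
        code=code.strip(),
        C0_bact=values["bact"] * 1e5,
        bact_retention=BACT_RETENTION,
        flow_rate=values["rate"] * 1e-3,
        C0_cem=values["cem"] * 100.0,
        cem_retention=CEM_RETENTION,
        rounds=1 if prefix == "S" else 5,
        injected_pore_volumes=injected_pore_volumes,
    )


def format_scheme(scheme: GroutingScheme) -> str:
    """Reconstruct the compact code of a scheme (inverse of the parser)."""
    prefix = "S" if scheme.rounds == 1 else "M"
    # rates carry one decimal by convention (1.0, 1.5, 2.0)
    return (f"{prefix}-{scheme.C0_bact / 1e5:g}-{scheme.C0_cem / 100.0:g}"
            f"-{scheme.flow_rate / 1e-3:.1f}")


#: the registered treatment schemes of the simulation campaign
SCHEME_CODES = (
    "S-7.2-3-1.5", "S-7.2-5-1.5", "S-7.2-10-1.0", "S-7.2-10-1.5",
    "S-7.2-10-2.0", "S-7.2-15-1.5", "S-4.3-10-1.5",
    "M-4.3-10-1.5", "M-7.2-10-1.5", "M-7.2-10-1.0", "M-7.2-10-2.0",
    "M-7.2-3-1.5", "M-7.2-5-1.5", "M-7.2-15-1.5",
)


def list_schemes() -> list[GroutingScheme]:
    return [parse_scheme(code) for code in SCHEME_CODES]


def load_scheme(source: str) -> GroutingScheme:
    """Load a scheme from a compact code or a YAML config file.

    A YAML file carries keys mirroring :class:`GroutingScheme` fields; a
    ``code`` key may substitute for all of them, with the remaining keys
    acting as overrides.
    """
    if os.path.exists(source) or source.endswith((".yml", ".yaml")):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemeParseError(f"scheme file {source!r} is not a mapping")
        if "code" in raw:
            base = parse_scheme(raw.pop("code"))
            return replace(base, **raw) if raw else base
        try:
            return GroutingScheme(**raw)
        except TypeError as exc:
            raise SchemeParseError(f"scheme file {source!r}: {exc}") from None
    return parse_scheme(source)


def save_scheme(scheme: GroutingScheme, path: str) -> None:
    """Write a scheme as a YAML mapping (round-trips through load_scheme)."""
    data = {f.name: getattr(scheme, f.name) for f in fields(scheme)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# injection / retention stages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One injection or retention phase with its boundary conditions.

    ``inlet_conc`` gives the composition of the injected fluid for every
    transported species; species listed in ``dirichlet_species`` are held at
    that value on the inlet face (advective plus diffusive exchange), the
    others enter only advectively (zero diffusive flux).  Retention stages
    have zero inlet flux and zero-flux boundaries all around.
    """

    kind: str                       # inject_bacteria | retention | inject_cementation
    duration: float                 # s
    inlet_flux: float               # Darcy flux at the inlet face, m/s
    inlet_conc: dict
    dirichlet_species: tuple = ()
    resets_urease_clock: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("inject_bacteria", "retention",
                             "inject_cementation"):
            raise ValueError(f"unknown stage kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("stage duration must be positive")
        if self.kind == "retention" and self.inlet_flux != 0.0:
            raise ConfigurationError("retention stages carry zero inlet flux")
        missing = set(SPECIES) - set(self.inlet_conc)
        if missing:
            raise ConfigurationError(f"inlet_conc missing species {missing}")

    @property
    def is_injection(self) -> bool:
        return self.kind != "retention"
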