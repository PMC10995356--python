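# Methods

## Scope and geometry

`biogrout` models staged MICP grouting of a water-saturated sand column as a
one-dimensional vertical problem: a uniform finite-volume grid along the
column axis (default 10 cm length, 5 cm diameter, 100 cells), with the
grouting inlet at the top face and a free outlet at atmospheric pressure at
the bottom. The physical experiment injects through a 1 cm hole in the top
cap; the 1-D reduction spreads the inlet flux over the whole cross-section
and therefore cannot represent the radial spreading, the locally elevated
velocities under the hole, or any non-axisymmetric fingering. Reported
quantities are the observation-point series (the cell containing the column
mid-height) and per-cell depth profiles, which is where a 1-D description is
most defensible.

## Processes

**Flow.** Darcy flow with concentration-dependent liquid density
(ρ_l = ρ_w + 0.0154994·C_urea + 0.0867338·C_Ca + 0.0158991·C_NH4, kg/m³ per
mol/m³). Flow is quasi-steady: the incompressible pressure equation is
re-solved every time step on the current permeability field (harmonic-mean
face permeabilities, arithmetic face density in the gravity term), dropping
storage and reaction source terms — density varies by ≲11 % and porosity by
percent over hours, so transients are negligible against the stage
durations. Retention stages are static reaction periods with u ≡ 0; we do
not let gravity drain the column between injections.

**Bacteria.** Two pools on the same concentration scale: suspended cells
advect with the Darcy flux and diffuse (D_bacl defaults to the molecular
value, as no separate measurement is available); attached cells are
immobile. Attachment is irreversible first-order (k_att = 1.52×10⁻³ s⁻¹,
i.e. a ~11 min attachment time-scale, so nearly the entire suspended charge
attaches during the 1 h post-injection rest). Both pools decay at
k_d = 3.18×10⁻⁷ s⁻¹. Growth is deliberately excluded: suspensions are
pre-cultured to their working concentration and the treatment lasts hours,
not generations. The local exchange–decay system is linear and is advanced
by its exact exponential solution, so the total pool obeys
d(C_bacl + C_bacs)/dt = −k_d(C_bacl + C_bacs) to round-off regardless of the
step size.

**Kinetics.** The overall ureolysis rate is
k_urea = u_sp·C_bact·C_urea/(k_m + C_urea)·f_d(t). `u_sp` (1.4×10⁻⁸
mol·m⁻³·s⁻¹ per cell/mL) is a lumped urease capacity per unit bacterial
concentration; with the reference inoculum of 7.2×10⁵ cells/mL the maximum
rate is U_max ≈ 1.008×10⁻² mol·m⁻³·s⁻¹. C_bact is the total (attached +
suspended) concentration by default; a configuration switch restricts it to
attached cells only. Urease deactivates exponentially, f_d =
exp(−(t−t_c)/t_d) with t_d = 288 000 s and t_c the start of the current
round's cementation injection; an alternative form exp(−k_d(t−t_c)) is
selectable (`urease_decay_mode="decay_rate"`), but with k_d ≈ 3×10⁻⁷ s⁻¹ it
leaves urease effectively undecayed within a 10 h stage, which contradicts
the declining-activity phenomenology the deactivation factor exists to
capture — hence the time-constant form is the default.

**Solutes.** Urea, Ca²⁺ and NH₄⁺ follow advection–dispersion–reaction
transport in the pore fluid. The longitudinal dispersion coefficient is
α_L·|v| + D_m; α_L defaults to 0 (pure molecular diffusion, D_m = 2×10⁻⁹
m²/s) because no dispersivity measurement is available for this sand — it
remains configurable, and the oracle tests exercise the dispersive branch.
Reaction consumes one urea and one Ca²⁺ and releases two NH₄⁺ per mole
hydrolysed. The cementation solution is fresh: its inlet NH₄⁺ concentration
is zero.

**Medium evolution.** Calcite is immobile and accumulates at
m_CaCO3·n·k_urea (k_urea is per pore volume; the explicit n converts to bulk
volume). Porosity decreases by the deposited calcite volume
(m_CaCO3/ρ_CaCO3 ≈ 3.69×10⁻⁵ m³/mol) and permeability follows Kozeny–Carman
with the mean grain diameter d_m = √(180·k₀(1−n₀)²/n₀³) = 45 µm, derived
once so that k(n₀) = k₀ exactly (k₀ = 2×10⁻¹² m², n₀ = 0.40). A porosity
floor n_min = 0.01 keeps the law finite in fully clogged cells; runs report
whether the floor was ever hit (it is not, under any default scheme).

## Numerics

Operator splitting per time step: flow → bacterial transport + exact
exchange → solute transport → reaction + medium update. Transport uses a
conservative finite-volume update of the pore mass n·C·dx with first-order
upwind advection (a van Leer flux-limited reconstruction is available via
`advection_scheme="vanleer"`) and central dispersion; the inlet face carries
the injected composition advectively, Dirichlet species additionally couple
through a half-cell diffusive flux, and the outlet is advective with zero
diffusive flux. The time step satisfies a combined explicit stability bound
(advective Courant plus three times the diffusion number ≤ 0.9, the factor
three covering the half-cell inlet conductance), is capped at 300 s during
retention, and is truncated exactly at stage boundaries, making runs
bit-for-bit deterministic.

The reaction substep is *exact* rather than explicit: for frozen bacteria
the Michaelis–Menten depletion over a step has the closed form
C(τ) = k_m·W(C₀/k_m·e^{(C₀−U_maxτ)/k_m}) (principal Lambert-W branch), with
the urease-deactivation and bacterial-decay exponentials folded into an
effective step duration τ. Where the exponential overflows (C₀ ≫ k_m) the
implicit relation is solved by Newton iteration instead. Consumption is
additionally capped by the calcium available in the cell, and the same
per-cell reacted amount drives solute sinks, NH₄⁺ release, calcite,
porosity and permeability — which is why the calcite/calcium mole balance
closes to round-off. This construction removes any kinetic time-step
restriction and makes the zero-flow solver agree with an independent stiff
ODE integration to ~10⁻¹⁰ relative.

Porosity change does not rescale resident concentrations (the transport
equation keeps n outside the time derivative), so pore-fluid mass displaced
by growing calcite leaves the books explicitly; the audit accounts for it as
a separate "expelled" term and the species balances then close to machine
precision (gated at 10⁻⁶).

Accuracy checks on the defaults: halving the time step moves end-of-run
observation values by < 1 %; doubling the grid to 200 cells moves
end-of-run calcite by < 2 %; the mid-column breakthrough curve of a passive
front at Péclet 50 matches the Ogata–Banks solution to 1.5 % L² error with
upwind (0.4 % with the van Leer limiter).

## Study conditions and what the defaults emulate

The default schemes are the 14-entry campaign registry (single- and
five-round treatments spanning bacterial concentration 4.3/7.2×10⁵
cells/mL, cementation 300–1500 mol/m³, rate 1.0–2.0×10⁻³ m/s). Retention
times are 1 h after the bacterial injection and 10 h after the cementation
injection; rounds follow each other without a gap. The campaign tables give
no injected volume, so each injection delivers 1.0 pore volume — standard
biogrouting practice and shared by every scheme, keeping between-scheme
comparisons volume-consistent. This is the single most consequential
modelling choice: with ~1 PV of suspension the attached pool saturates near
the injected concentration C0_bact for *every* injection rate, so treatment
strength scales with the inoculum (calcite and permeability-effect ratios
between bacterial concentrations ≈ 1.65) but is nearly rate-independent,
and a 10 h round hydrolyses at most U_max·t ≈ 360 mol/m³ of urea (a few
percent permeability reduction per round). Campaign set-ups that supply
bacteria continuously for hours accumulate attached cells far beyond
C0_bact and reach tens-of-percent reductions per round with strong rate
sensitivity; the simulator reproduces such regimes only if
`injected_pore_volumes` is raised accordingly. Passing the default tests
therefore validates the mechanisms and their coupling under the 1-PV
protocol, not the absolute magnitudes of any particular laboratory or 3-D
simulation campaign.

## Known limitations

- 1-D: no radial flow from the inlet hole, no preferential paths.
- No carbonate speciation or pH: precipitation is slaved to ureolysis
  stoichiometry, so supersaturation kinetics and inhibition are absent.
- No biofilm pore-volume: porosity responds to calcite only.
- No detachment or shear erosion of attached cells or calcite.
- Retention stages are strictly no-flow; gravity drainage between
  injections is not modelled.
- First-order upwind advection smears fronts by numerical diffusion at 100
  cells; use the van Leer scheme or more cells for front-sharpness studies.
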