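# biogrout

A one-dimensional bio-chemo-hydro column simulator for **microbially induced
calcite precipitation (MICP)** grouting of saturated sand.

MICP treats soil by injecting a suspension of ureolytic bacteria followed by
a *cementation solution* (equimolar urea + Ca²⁺). Bacteria attach to grain
surfaces and hydrolyse urea; the carbonate produced precipitates with calcium
as calcite, which clogs pores and lowers the permeability of the treated
column. `biogrout` simulates this staged treatment on a vertical sand column
(10 cm tall, 5 cm diameter by default) and predicts calcite, attached
bacteria, porosity and permeability over time and depth, so that grouting
recipes — bacterial concentration, cementation concentration, injection
rate, number of rounds — can be compared before going to the lab.

## Model

The column is a saturated porous medium under quasi-steady Darcy flow,

$$u = -\frac{k}{\mu}\left(\nabla P - \rho_l g\right),$$

with the liquid density a linear function of the solute concentrations.
Suspended bacteria $C^{bacl}$ advect and diffuse, attach irreversibly to
grains at first order ($k_{att}$), and both pools decay uniformly ($k_d$):

$$\partial_t C^{bacs} = k_{att} C^{bacl} - k_d C^{bacs}, \qquad
  \partial_t C^{bacl}\big|_{exch} = -(k_{att}+k_d)\, C^{bacl}.$$

Ureolysis is Michaelis–Menten in urea, proportional to the total bacterial
concentration, and damped by exponential urease deactivation whose clock
starts at the cementation injection of the current round ($t_c$):

$$k_{urea} = u_{sp} C^{bact}\,\frac{C^{urea}}{k_m + C^{urea}}\,
  e^{-(t-t_c)/t_d}.$$

Urea, Ca²⁺ and NH₄⁺ obey advection–dispersion–reaction transport with the
stoichiometry CO(NH₂)₂ + 2H₂O + Ca²⁺ → CaCO₃↓ + 2NH₄⁺. Calcite is immobile;
it accumulates as $\partial_t C_{CaCO_3} = m_{CaCO_3}\, n\, k_{urea}$,
consumes porosity as $\partial_t n = -\partial_t C_{CaCO_3}/\rho_{CaCO_3}$,
and permeability follows Kozeny–Carman,
$k = \tfrac{d_m^2}{180}\, n^3/(1-n)^2$.

A treatment scheme is written `{S|M}-{bact}-{cem}-{rate}`: single or
multi-round (5), bacterial concentration in 10⁵ cells/mL, cementation
concentration in 100 mol/m³, inlet Darcy flux in 10⁻³ m/s. Each round is
*bacterial injection → 1 h retention → cementation injection → 10 h
retention*, with each injection delivering one pore volume by default.

## Worked example

```sh
$ biogrout run --scheme S-7.2-10-1.5
scheme S-7.2-10-1.5: 488 steps, end time 39653 s
observation point (cell 50):
  calcite        12.58 kg/m^3
  attached cells 7.077e+05 cells/mL
  porosity       0.3954 (1.16% reduction)
  permeability   1.902e-12 m^2 (4.92% reduction)
```

One round with 7.2×10⁵ cells/mL bacteria and 1000 mol/m³ cementation
solution at 1.5×10⁻³ m/s: at the column mid-height, essentially the whole
injected bacterial charge ends up attached (7.08×10⁵ cells/mL), the 10 h
reaction deposits 12.6 kg/m³ of calcite, and permeability falls 4.9 % from
its initial 2×10⁻¹² m². Comparing schemes:

```sh
$ biogrout compare --schemes S-4.3-10-1.5 --schemes S-7.2-10-1.5
              calcite_obs_kg_m3  k_reduction_pct  ...  k_reduction_pct_ratio
S-4.3-10-1.5              7.569            2.985  ...                      1
S-7.2-10-1.5              12.58            4.920  ...                  1.648
```

Raising the bacterial concentration from 4.3×10⁵ to 7.2×10⁵ cells/mL
multiplies the calcite yield by 1.66 and the permeability-reduction effect
by 1.65 — the treatment strength scales with the inoculum. `biogrout run
--out DIR` writes the observation-point time series, final depth profiles,
per-round summaries and a full parameter manifest as CSV/YAML.

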