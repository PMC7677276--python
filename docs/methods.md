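# Methods

This note documents the model implemented in `ocupbpk`: its structure,
assumptions, parameter conventions, numerical choices, and what the
synthetic data used in the tests can and cannot show.

## Model structure

### Pre-corneal compartment

Instilled liquid mixes with the resident tear film (baseline 7.5 µL). The
pre-corneal sac holds at most `V_max` = 35 µL; anything beyond overflows
instantly, so the retained dose fraction of an instilled volume `V_i` is
`(min(V_i + V_base, V_max) − V_base) / V_i` (0.55 for a 50 µL drop).
Ointments adhere to the surface and are exempt. The retained excess volume
then drains back to baseline at the drainage rate, `V(t) = V_base +
(V_0 − V_base)·e^(−k_drain·t)`; tear concentration, the membrane fluxes
from tears and the tear-flow turnover term all use `V(t)`. Holding the
volume constant at baseline instead would put a saturated 50 µL drop at
~3.7× its own solubility immediately after dosing, which is unphysical, so
the dynamic volume is used throughout.

Drug (and suspended particles alike) leave the tears by first-order
nasolacrimal drainage (`k_drain` = 1 min⁻¹) plus tear-flow turnover
(`TF/V(t)`, TF = 1.12 µL/min); both routes are swallowed and land in a
well-mixed stomach compartment that absorbs into the central compartment at
a first-order rate (default 1 h⁻¹ — full intestinal transit modeling is out
of scope, and this route contributes little to ocular exposure).

### Ocular cascade

The eye topology is a reconstruction (the commercial model's full structure
is not published) and is overridable via the `interfaces` argument of
`assemble_odes`:

- corneal route: tears ↔ cornea epithelium ↔ stroma ↔ aqueous humor;
- conjunctival/scleral route: tears ↔ conjunctiva ↔ sclera ↔ choroid ↔
  retina ↔ vitreous humor;
- exchange links: aqueous humor ↔ iris–ciliary body, vitreous ↔ aqueous
  humor.

Each membrane flux is `Perm · SA · (C_donor − C_receiver)` with the
permeability of the inner tissue governing its interface; the vitreous ↔
AH link uses the vitreous permeability (the published list is ambiguous on
whether the "AH permeability" describes AH turnover or the AH–vitreous
interface; here it governs the corneal-stroma → AH step, the optimized
anterior pathway). The corneal chain uses the cornea surface area
(1.763 cm²); all other interfaces default to 1.0 cm² because no other
areas are printed — both are scenario keys. Tissue volumes (needed only to
convert amounts to concentrations) are standard rabbit anatomy defaults,
each overridable: AH 0.31 mL, vitreous 1.5 mL, cornea epithelium 0.015 mL,
stroma 0.055 mL, conjunctiva 0.2 mL, iris–ciliary body 0.06 mL, sclera
0.18 mL, choroid 0.065 mL, retina 0.05 mL.

Vascularized tissues (conjunctiva, iris–ciliary body, choroid, retina) lose
drug to the central compartment by first-order systemic absorption rates on
tissue amount (s⁻¹, per unit analysis of the published values). Systemic
disposition is one-compartmental: plasma concentration = amount/(Vc·BW)
(body weight default 2.5 kg), elimination = CL·C_plasma. The blood/plasma
ratio is carried as drug metadata but does not enter the dynamics; all
transfers are amount-conserving.

### Dosage-form source terms

*Ointment.* Release into tears at `SA·k_H·t^(−1/2)`; base removal at
`dose/application_time`, routed (with any entrained unreleased drug) to the
stomach. Both drains act on the unreleased reservoir simultaneously, so
the reservoir empties slightly before the nominal application time when
release is non-negligible. Released-but-unabsorbed drug in the tears is
*not* carried off with the base; it follows normal drainage.

*Suspension.* The dose is split at administration into dissolved
(`min(dose, C_s·V_i)`) and suspended mass. Particles dissolve by the
Lu–Frisella–Johnson monodisperse model,
`rate = (3D/(ρ·h·r₀))·m₀^{1/3}·m^{2/3}·(C_s − C)`, with diffusion-layer
thickness `h` equal to the current particle radius capped at 30 µm,
particle density default 1.2 g/mL and an aqueous diffusion coefficient
default 5×10⁻⁶ cm²/s (distinct from the in-base diffusion coefficient used
by the release-constant estimate — different media). Published particle
sizes are mean *diameters*; `Formulation.particle_radius` is half the
quoted size.

## Units

All external parameters are entered in the customary units of ocular PK
tables (µL/min, min⁻¹, L/h, h, µm ...) and converted once onto an internal
mg/mL/cm/s system at scenario compilation; conversions are involutive to
1e-12 relative.

## Numerics

- Stiff-capable adaptive integration (LSODA), default `rtol` 1e-8, `atol`
  1e-12 mg; output by dense interpolation on the requested grid (default
  0.05 h spacing over 24 h, 481 points).
- The `t^(−1/2)` release rate is singular at zero; the right-hand side
  clamps `t` to a floor (default 0.1 s). The first-step release error is
  bounded by `SA·k_H·√floor` (~1.5×10⁻⁶ mg for the Flm preset) and the
  floored rate is integrated exactly when locating exhaustion.
- Because both ointment drains depend only on `t`, the reservoir-exhaustion
  time is the root of a quadratic in `√t` and is computed analytically; the
  integration is split there into two smooth segments (a state-gated switch
  makes multistep solvers thrash on the discontinuity).
- The particle–solution exchange stays linear in `(C_s − C)` through
  saturation, so transient supersaturation recondenses onto existing
  particles instead of chattering at the constraint; with no particles
  present there is no precipitation. Below ~10·atol of suspended mass the
  exchange is switched off (the `m^{2/3}` Jacobian is singular at zero) and
  the remainder drains as solid.
- Every transfer moves mass between explicit states; losses accumulate in
  ledger states (drainage, overflow, ointment removal, systemic clearance),
  so the reported mass-balance residual measures pure integration error
  (~1e-14 at default tolerances; halving tolerances changes the AH AUC by
  <0.1%).
- Tmax ties break to the earliest time; AUC is linear-trapezoidal on the
  output grid with no extrapolation to infinity.

## Fitting

`fit_ointment` minimizes weighted residuals (`1/y` weighting by default,
the PK convention for concentration-proportional error) between simulated
and observed AH concentrations over bounded, log-transformed parameters,
with 5 seeded Latin-hypercube multi-starts — a reproducible replacement
for the manual optimization used in the original case studies.
Non-convergence is reported explicitly with the best point found. Default
bounds: k_H ∈ [1e-8, 1e-3] mg·s^−1/2·cm^−2, application time ∈ [0.25, 24] h,
application SA ∈ [0.1, 5] cm².

## Synthetic data

The in vivo AH profiles behind the published case studies were digitized
from third-party figures and are not shipped. `generate_synthetic_observed`
replaces them: it simulates a scenario and applies multiplicative
log-normal noise with unit mean and chosen CV per observation (default
conditions for the recovery studies: truth k_H = 2.7×10⁻⁶ and application
time 5 h, 10% CV, 10 sampling times over 24 h). `random_scenario` perturbs
every transfer parameter log-normally (geometric SD ≈ 1.3) around the Flm
preset for property testing. These fixtures exercise the estimation and
conservation machinery under known ground truth; they do not capture
inter-animal variability, assay error structure, sparse/censored sampling,
or model misspecification, so passing recovery tests demonstrates
identifiability under the model, not predictive accuracy on real data.

## Dosage-form comparison

The headline comparison (acceptance script) simulates 50 µg Flm as the
0.1% ointment versus the 0.1% suspension at the same dose over 24 h. The
package uses the verified coarse suspension (PS 10.4 µm) as comparator,
which yields a +94% AH AUC increase for the ointment, matching the
reported ~100%; against the fine 2 µm suspension the increase is +52%
(finer particles dissolve essentially instantly, so their exposure
approaches the solution limit and the ointment's relative advantage
shrinks). Both numbers are recomputed by `examples/02_dosage_form_comparison.py`.

## Known limitations

- The compartment topology, tissue volumes and non-corneal interface areas
  are reconstructions/defaults, not published values; absolute tissue
  concentrations outside the AH should be treated as qualitative.
- No tear pH dynamics, melanin binding, blink-resolved dynamics (blinking
  enters only through the constant application-SA assumption), polydisperse
  particle distributions, or human physiology.
- The Dex preset reuses the Flm ocular physiology with literature Dex drug
  properties; only its ointment parameters (30 µL of 0.1%, application time
  3.5 h, k_H = 1.5×10⁻⁵) are published.
- GI handling of swallowed drug is a single first-order absorption step.
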