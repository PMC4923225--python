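# Methods

`lungno` simulates the transport of nitric oxide (NO) in the human lungs
with a morphological model: every one of the 24 generations of a symmetric,
dichotomously branching Weibel tree is represented, the walls of the
conducting airways are resolved as reacting tissue layers, and the exhaled
NO fraction (FE_NO) is obtained by integrating a one-dimensional
convection–diffusion equation along the tree over a full respiratory cycle.
This note records the model, its assumptions, the numerical choices, and
what the synthetic scenarios do and do not establish.

## Geometry

**Rest morphometry.** Generation `i` (0 = trachea, 23 = terminal alveolated
ducts) holds `2^i` identical airways of length `L_i`. Two per-generation
cross-sections are carried: the total section `Ω_i` (all gas, lumen plus
alveoli; `Ω_i L_i` is the generation's gas volume) and the flow section
`Ω′_i` (lumen only — alveoli store gas but do not transmit it axially).
The packaged table (`lungno/data/weibel_morphometry.csv`) integrates to a
rest volume of 3700 ml. Alveoli appear from generation 17 onward
(`Ω_alv,i = Ω_i − Ω′_i > 0`).

**Layered walls.** Generations 0–18 carry an axisymmetric layered wall:
epithelium (rest thickness 15 µm), smooth muscle (30 µm), and an optional
mucus film lining the epithelium (pathological scenarios; never in
generations 19–23, whose walls are alveolar). Radii are ordered
`R_µ ≤ R_L < R_E < R_M` from the gas-facing mucus surface to the outer
muscle surface, with `R_L = sqrt(Ω′_i/(π 2^i))` at rest.

**Bronchoconstriction.** Smooth-muscle contraction is modeled as an
axisymmetric reduction of the outer radius, `R_M → (1−α) R_M`, with each
annular layer conserving its cross-sectional area (tissue is
incompressible; the epithelium wrinkles rather than compresses). The inner
radii follow `R_x → sqrt(R_x² + ((1−α)²−1) R_M²)`; the radicand vanishing
defines the occlusion limit `α_max = 1 − sqrt(1 − (R_µ/R_M)²)`. Users more
often prescribe the lumen-area reduction `β = 1 − R_µ²/R_µ,0²`, mapped to
`α` exactly; `β = 1` is occlusion. Constriction profiles default to
starting at generation 2 (the trachea and main bronchi are assumed not to
constrict), with the start generation exposed as an option.

**Respiratory cycle.** The lungs inflate uniformly: all cross-sections
share one scale factor `s` — `1 + Dil·θ` during inspiration, `1 + Dil`
during breath-hold, `1 + Dil(1−θ)` during expiration — where
`Dil = Q_in·t_in / V` is the inspired volume relative to the rest volume
and θ is the phase time normalised by the phase duration. Airway lengths
are fixed, so gas-facing radii scale as `sqrt(s)` and the outer wall radii
follow from layer-area conservation at every instant: walls thin as the
lung inflates. Exchange surfaces are `S_air,i = 2^i·2π R_µ,i(θ) L_i`
(airway wall, generations 0–18) and `S_alv,i = Ω_alv,i(θ) L_i · 6/d_alv`
(hemispherical alveoli of diameter `d_alv` = 200 µm). Pre- and post-cycle
volumes must match (`Q_in t_in = −Q_ex t_ex`), which the breathing-pattern
type enforces.

## Air flow

Incompressible flow with uniform inflation makes the flow quasi-steady:
`Q_i(ζ) = Q0 (1 − Σ_{j<i} f_j − f_i ζ)` with `f_i = L_i Ω_i / V` the
volume fractions of the (possibly altered) rest geometry, `ζ = z/L_i`, and
`Q0` the mouth flow of the phase. The per-generation Péclet number
`Pe_i = L_i Q_in/(D_NO,air Ω′_i)` falls from ~15000 in the trachea to
~0.016 in generation 23, crossing 1 between generations 17 and 18: the
proximal tree is convection-dominated, the acinus diffusion-dominated,
which is what makes distal back-diffusion of NO possible.

## Wall exchange

**Airway walls.** NO is produced volumetrically in the epithelium (rate
`Pr`, identical in every generation), consumed by a first-order reaction
(constant `k`) in both tissue layers, diffuses with the liquid-water
diffusivity `D_NO,t`, and is scavenged instantly by hemoglobin at the
muscle–blood interface (perfect sink). The mucus film is inert. Treating
the wall as a planar quasi-steady slab (thickness ≪ radius, diffusion time
≪ phase durations) gives a boundary-value problem whose closed-form
solution is hyperbolic in the layer moduli `Ha = sqrt(k/D) δ_M`,
`Hã = sqrt(k/D) δ_E`, `Mu = sqrt(k/D) δ_µ` (Hatta numbers: reaction rate
vs diffusion across the layer; ≈0.74 and ≈0.37 at rest). The exchange flux
into the lumen is affine in the lumen concentration `C` (gas volume
fraction):

    J_air(C) = a − b·C
    a = γ Pr sqrt(D/k) · (cosh(Ha+Hã) − cosh Ha) / (sinh(Ha+Hã) + Mu cosh(Ha+Hã))
    b = γ λ sqrt(kD) · cosh(Ha+Hã) / (sinh(Ha+Hã) + Mu cosh(Ha+Hã))

with `λ` the Henry partition tissue:gas and `γ` the gas molar volume
(2.545×10⁴ cm³/mol, the ideal-gas value at 37 °C and 1 atm — note that the
same number is sometimes quoted with a 319.15 K label, which is
inconsistent with the ideal-gas law; 310.15 K is the temperature that
reproduces it). The mucus-free case is the exact `Mu → 0` limit of the
same expression, so one code path serves both. Because `a` and `b` are
evaluated from the instantaneous thicknesses, constriction (thicker
layers, longer residence time) raises the flux density `J` while shrinking
the exchange surface by `sqrt(1−β)`; mucus acts purely as a barrier and
lowers `a`.

Two independent oracles guard this closed form: a second-order
finite-difference boundary-value solver with Richardson extrapolation
(agreement ≤ 1e−6 relative over a grid of `(Ha, Hã, Mu, C)`), and an
algebraic identity check against the equivalent exponential-form
transcription at random parameter points (agreement to machine precision).
The full wall profile (piecewise hyperbolic) is also exposed; its boundary
fluxes satisfy produced = to-lumen + to-blood + consumed to 1e−9 relative.
At rest about 7 % of the epithelial production is consumed in the wall
(rising to ~20–25 % under strong constriction), consistent with the
"around 10 %"/"up to 25 %" orders usually quoted.

**Quasi-steady validation.** A transient axisymmetric solver integrates
the radial diffusion–reaction problem in the hollow-cylinder wall
(vertex-centred finite volumes, LSODA with analytic banded Jacobian) after
a 0 → 5 ppb lumen concentration step, starting from the steady zero-lumen
profile. Under strong constriction (β = 0.9) the post-transient flux
differs from the planar quasi-steady law by 2 % (generation 5), 5 %
(generation 10), 8 % (generation 15); only at generation 18, where the
thickened wall reaches ~65 % of the lumen radius, does curvature push the
difference to ~12 %. The transient relaxes with time constant
`1/(k + D π²/δ²) ≈ 0.15–0.25 s`, an order of magnitude below the phase
durations — the quasi-steady planar law is adequate wherever the layered
wall description itself is sensible.

**Alveolar exchange.** The alveolar source is lumped:
`J_alv(C) = (P_alv − U_alv·C)/S_alv,tot(θ)`. Its equilibrium
`P_alv/U_alv ≈ 2.03 ppb` sets the acinar NO plateau and is independent of
inflation.

## Lumen transport

The cross-sectionally averaged NO fraction obeys, per generation,

    Ω_i(t) ∂C/∂t + Q_i(z) ∂C/∂z = D_NO,air Ω′_i ∂²C/∂z² + (J_alv S_alv + J_air S_air)/L_i

(the diffusive term carries `Ω′`, not `Ω`: axial transport passes through
the lumen only). The solver integrates this dimensional form phase by
phase with the phase's scale factor `s(t)`; this is algebraically
equivalent to the per-phase dimensionless forms in `θ` and `ζ` and avoids
transcribing them separately.

**Discretization.** Each generation has `n` equally spaced ζ-nodes
(default 20); the junction between generations is a single shared node, so
the 24 generations form one tridiagonally coupled chain of
`24n − 23` unknowns. A vertex-centred finite-volume form is used with
first-order upwind convective face fluxes and second-order centred
diffusive face fluxes weighted by the instantaneous `Ω′` of the owning
generation. Junction continuity of concentration (shared node) and of the
*total* axial diffusive flow `D Ω′ ∂C/∂z` (the only convention that
conserves mass across cross-section jumps) then hold by construction, and
the spatial scheme is exactly conservative. Boundary conditions: the mouth
node is held at zero during inspiration (NO-free inspired air) and is a
pure convective outlet (zero diffusive gradient) during breath-hold and
expiration; the distal end of generation 23 is closed to diffusion.

**Time integration.** The semi-discrete system is linear but stiff (axial
diffusion in the short distal generations relaxes on milliseconds, the
alveolar source on seconds). LSODA with an analytically assembled banded
Jacobian integrates each phase (relative tolerance 1e−7); upwinding plus
the implicit stiff mode preserve positivity at the default resolution.
Phases are chained, each starting from the previous end state; a cycle
starts from zero NO everywhere (the measurement protocol: the subject
inhales NO-free air).

**Diagnostics.** A mass-balance audit compares the change of the total NO
inventory against time-integrated sources minus mouth outflow (trapezoidal
quadrature over the sampled trajectory); the defect is ~4e−5 of the
production at default settings and shrinks with denser sampling.
Doubling the grid to 40 points per generation moves the end-expiration
FE_NO by 0.22 %.

## Experiments and scenario conventions

* **Classical maneuver** (500 ml/s × 2 s inspiration, no hold, 50 ml/s ×
  20 s expiration): end-expiration FE_NO,50 = 15.5 ppb at default
  resolution, with the expected fast rise to ~14 ppb in the first seconds.
* **Flow sweep**: expiration duration is stretched to keep the expired
  volume equal to the inspired volume at every flow; FE_NO falls
  monotonically from ~21 ppb at 25 ml/s toward ~5 ppb at 500 ml/s.
* **Breath-hold sweep**: holds ≥ ~5 s produce an early FE_NO maximum
  (accumulated bronchial NO washing out first), growing with the hold and
  bounded by the airway-wall equilibrium `a/b` (~370 ppb at rest).
* **Constriction comparisons**: `ΔFE_NO,50`, `ΔJ` (ζ-averaged flux density
  in the last constricted generation at end-expiration) and `ΔFlux`
  (surface-integrated flow in that generation) are relative differences
  (unhealthy − healthy)/healthy, both lungs breathing the identical
  pattern; the healthy reference carries neither constriction nor mucus.
* **Cyclic regime**: a single cycle from zero NO cannot exhibit the distal
  2–3 ppb plateau "at all times" — the acinus needs roughly one cycle to
  charge. The simulator therefore accepts `n_cycles`; the plateau and the
  permanent mouthward distal gradient (back-diffusion) are asserted on the
  second chained cycle, while FE_NO numbers are reported from the
  single-cycle protocol.

## Defaults and parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `D_NO,air` | 0.217 | cm²/s | NO diffusivity in air |
| `D_NO,t` | 3.3e−5 | cm²/s | NO diffusivity in tissue (water) |
| `k` | 2.001 | 1/s | first-order tissue consumption |
| `Pr` | 5.17e−12 | mol/(cm³·s) | epithelial NO production |
| `λ` | 1.64e−6 | mol/cm³ | Henry partition tissue:gas |
| `γ` | 2.545e4 | cm³/mol | gas molar volume (37 °C, 1 atm) |
| `P_alv` | 3.167e−6 | ml NO/s | total alveolar production |
| `U_alv` | 1558 | cm³/s | alveolar consumption conductance |
| `δ_E,0`, `δ_M,0` | 15, 30 | µm | rest epithelium/muscle thickness |
| `d_alv` | 200 | µm | alveolar diameter |
| `n` | 20 | – | grid points per generation |

All lengths are cm, areas cm², volumes cm³ (= ml), times s, concentrations
gas volume fraction (1 ppb = 1e−9); unit conversions happen only at I/O
boundaries.

## Design choices where the design was open

* Generations 19–23 carry no wall radii at all (arrays stop at 18), so any
  attempt to use layered-wall machinery distally fails loudly instead of
  returning zeros.
* Generations 17–18 are transitional: they carry both a layered wall
  (`S_air > 0`) and alveoli (`S_alv > 0`); both exchange laws are applied
  there.
* Mucus annuli are conserved under constriction exactly like tissue
  layers, and a mucus film reduces the flow cross-section
  (`Ω′ = 2^i π R_µ²`) even without constriction.
* The geometry consumes the printed cross-section columns at face value
  rather than the rounded diameter column (the derived occlusion limits
  and Péclet numbers are consistent with the former, not the latter).
* FE_NO is read at the mouth node (generation 0, ζ = 0); no extra-thoracic
  dead space is modeled.
* The Péclet column anomaly of the trachea (printed 15083 vs recomputed
  15109, a 0.17 % rounding artifact of `Ω′`) is documented, and generation
  0 is not used as a numeric reference.

## Known limitations

Symmetric branching only (no inter-subject variability, no asymmetry);
axisymmetric constriction without airway closure or wrinkling geometry;
blood is a perfect NO sink (no hemoglobin kinetics); production `Pr` is
generation-independent; the lumen concentration is cross-sectionally
homogeneous (no radial lumen resolution, no turbulence); no pressure–flow
mechanics (flow is prescribed, incompressible and quasi-steady). The
scenario generator emulates idealised maneuvers with perfectly constant
flows; real FE_NO recordings include flow jitter, dead-space artifacts and
ambient NO, so passing the property suite shows internal consistency of
the model and agreement with the literature's characteristic magnitudes,
not patient-level predictive accuracy.
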