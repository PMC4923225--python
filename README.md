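# lungno

Morphological simulation of nitric-oxide (NO) transport in the human lungs.

Exhaled NO (FE_NO, parts per billion) is a routine clinical marker of
airway inflammation, yet connecting a measured FE_NO to what is happening
inside the bronchial tree requires a transport model. `lungno` implements
such a model for researchers in respiratory physiology and modelers of
airway gas exchange: a 24-generation symmetric Weibel lung in which

* every conducting airway wall (generations 0–18) is resolved as reacting
  tissue layers — epithelium (NO source), smooth muscle, optional mucus —
  yielding a closed-form exchange law instead of a fitted lumped rate;
* bronchoconstriction is modeled mechanistically as axisymmetric narrowing
  at conserved tissue volume (layers thicken as the lumen shrinks), and a
  mucus film can coat any conducting generation;
* gaseous NO in the lumen follows a 1D convection–diffusion equation along
  the whole tree through inspiration, breath-hold and expiration, with the
  geometry inflating and deflating uniformly in time.

## The model in brief

With `Ha = √(k/D) δ_M`, `Hã = √(k/D) δ_E`, `Mu = √(k/D) δ_µ` the Hatta
numbers of the muscle, epithelial and mucus layers, the wall-to-lumen flux
is affine in the lumen NO fraction `C`:

    J_air(C) = a − b C,
    a = γ Pr √(D/k) (cosh(Ha+Hã) − cosh Ha) / (sinh(Ha+Hã) + Mu cosh(Ha+Hã)),
    b = γ λ √(kD) cosh(Ha+Hã) / (sinh(Ha+Hã) + Mu cosh(Ha+Hã)),

the alveolar exchange is `J_alv(C) = (P_alv − U_alv C)/S_alv,tot`, and the
lumen balance per generation is

    Ω_i ∂C/∂t + Q_i ∂C/∂z = D_air Ω′_i ∂²C/∂z² + (J_air S_air + J_alv S_alv)/L_i,

solved on all generations with junction continuity of concentration and of
total diffusive flow (first-order upwind convection, second-order centred
diffusion, stiff implicit time integration). See `docs/methods.md` for the
full account.

## Worked example

The standard FE_NO maneuver (inspire NO-free air at 500 ml/s for 2 s,
exhale at 50 ml/s for 20 s), healthy lungs:

```sh
lungno simulate --out feno.csv
```

```json
{
  "feno_end_ppb": 15.497851297086614,
  "feno_peak_ppb": 15.497851297086614,
  "mass_residual": 3.916178577698434e-05,
  "points_per_generation": 20,
  "total_volume_ml": 3700.0382000000004
}
```

The mouth NO fraction rises quickly to ~14 ppb within the first seconds of
expiration and then creeps up to **FE_NO,50 = 15.5 ppb** at end-expiration
— inside the 10–20 ppb range reported for healthy adults. The mass-balance
audit (change of NO inventory vs integrated sources minus mouth outflow)
closes to 4 × 10⁻⁵ of the production.

Cumulative bronchoconstriction (homogeneous lumen-area reduction β = 0.9
from generation 2 up to a varying last generation):

```sh
lungno sweep-bc --extents 7,12,16,18 --beta 0.9 --out bc.csv
```

```
 last_generation  d_feno50      d_j    d_flux
               7 -0.009432 1.330778 -0.262943
              12 -0.060444 1.221683 -0.297442
              16 -0.021180 1.120045 -0.329583
              18  0.253752 1.075623 -0.343630
```

Reading the columns: constriction more than doubles the wall-to-lumen flux
*density* (`d_j` ≈ +1.1 to +1.3: thicker layers hold NO longer) while the
total flux falls (`d_flux` < 0: the exchange surface shrinks by
√(1−β) ≈ 0.32). The net FE_NO,50 response depends on where constriction
ends: negligible when confined to the proximal generations (tiny share of
the production), negative through the central/distal conducting zone, and
**positive** once constriction reaches past generation 16, where narrowed
airways block the permanent back-diffusion of NO toward the acinus and
redirect it to the mouth. A mucus film (`--mucus-um 5`) lowers all three
metrics — it is a barrier between the producing epithelium and the lumen.

Other entry points: `lungno sweep-flow` (FE_NO vs expiratory flow, volume-
matched), `lungno sweep-breathhold` (early FE_NO maximum growing with the
hold), `lungno wall-profile` (NO concentration across an airway wall), and
`lungno simulate --config scenario.yaml` for full scenario files (see
`lungno/config.py` for the schema). Everything is importable as a library
(`lungno.simulate_cycle`, `lungno.bc_experiment`, …) and is fully
deterministic.

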