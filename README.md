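# rampkin

Kinetic model generation from **transient flow-ramp campaigns** in coiled
tubular reactors — for process chemists and reaction engineers who want a
full multistep kinetic model from a few hours of automated flow
experiments instead of weeks of steady-state runs.

The package covers the complete workflow around a linear flow-ramp rig:

1. **Flow program** — a campaign decelerates the total flow linearly
   (default 10 → 1.5 mL min⁻¹ at 0.836 mL min⁻²) through a 5 mL,
   0.79 mm ID coil while online HPLC samples the effluent every 2 min.
   Each injection at clock time *t* is mapped to the residence time of
   the exiting fluid element by inverting the swept-volume integral

   L = ∫ₜ₋τ ᵗ u(t′) dt′,   u(t) = β(T)(u₀ − αt),   β(T) = 1 + α_v(T₁ − T₀),

   which for a linear ramp is a quadratic in τ_res (solved in closed
   form, with β correcting for solvent thermal expansion).

2. **Virtual rig** — a synthetic-data generator that runs the full
   factorial campaign (nucleophile equivalents 1.5/4/7 × 30/60/90/120 °C,
   12 ramps, 72 injections) through the reaction-network ODEs, with an
   optional seeded HPLC-like noise model.

3. **Kinetics** — the SNAr network of 2,4-difluoronitrobenzene (**1**) +
   pyrrolidine (**2**) → *ortho* (**3**), *para* (**4**) and bis (**5**)
   adducts, all four steps second order, with rate constants in the
   reference-temperature Arrhenius form
   k(T) = k_ref·exp[−(Eₐ/R)(1/T − 1/T_ref)], T_ref = 90 °C.

4. **Global fitting** — all profiles are fitted simultaneously by
   Levenberg–Marquardt (log-k parameterisation), optionally via the
   two-stage protocol (isothermal 90 °C fit of the k's, then a global
   refinement of all 8 parameters), with SEs, 95 % confidence
   half-widths, R², and AICc-based discrimination of candidate
   rate-order motifs.

5. **Dispersion** — Taylor–Aris dispersion with the coil dispersion
   ratio κ (correlated against De·Sc^0.5), the closed-vessel
   dispersed-plug-flow conversion, κ estimation from a step-response
   F-curve, and the resulting fractional bias ε ≤ 0 on rate constants
   fitted under a plug-flow assumption (ε ≈ −500 % · κk for a 1 mm tube
   in ethanol).

## Worked example

```python
import rampkin as rk

design = rk.CampaignDesign()                    # the 12-ramp default campaign
scheme = rk.snar_scheme()                       # built-in SNAr network
table = rk.run_campaign(design, scheme,
                        noise=rk.NoiseModel(0.02, 1e-4), seed=42)
fit = rk.fit_two_stage(table, scheme)

from rampkin.fitting import table1_style_report
print(table1_style_report(fit))
```

prints

```
step    k +/- SE (1e-2 M^-1 s^-1)   Ea +/- SE (kJ mol^-1)
step1   56.6 +/- 0.5                32.9 +/- 0.16
step2   2.7 +/- 0.095               35.4 +/- 0.86
step3   0.852 +/- 0.0096            39.4 +/- 0.44
step4   1.92 +/- 0.27               43.1 +/- 6
R^2 = 0.999456   SSE = 0.00016   n = 288
```

i.e. from one noisy (2 % relative sd) simulated campaign of 72
injections, the fit recovers the generating parameters
(k₁ = 57.9 × 10⁻² M⁻¹ s⁻¹, Eₐ₁ = 33.3 kJ mol⁻¹, …) to within a few
percent, with the *ortho*/*para* selectivity k₁/k₂ ≈ 21 and an R² of
0.9995 over all 288 concentration points. The companion dispersion
report quantifies how much each profile's lumped rate constant
k₁₂ = (k₁+k₂)·C₂,₀ is biased by coil dispersion at a conservative
κ = 0.15:

```
   ramp_id    k12_s  epsilon12_pct  masked12
 eq1.5_T30 0.010189      -0.476932     False
 eq1.5_T60 0.033582      -1.571894     False
 eq1.5_T90 0.090900      -4.254802     False
eq1.5_T120 0.211384      -9.894371     False
```

(`masked12` flags profiles whose substrate concentration barely varies,
which cannot inform k₁+k₂.)

The same workflow is available from the shell:

```bash
rampkin pipeline --config campaign.yaml --seed 42 --out-dir out/
```

writing `sample_table.csv`, `fit_report.json`/`.txt` and
`dispersion_report.csv` (see `rampkin --help` for the individual
`simulate` / `fit` / `discriminate` / `dispersion` verbs and
`src/rampkin/config.py` for the YAML schema with its defaults).

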