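# streamprod

Secondary production of stream invertebrate communities: instantaneous-growth
estimation with paired bootstrap uncertainty, Boltzmann–Arrhenius temperature
scaling, and resource-corrected temperature dependences.

## The problem

Warming changes how much animal biomass ecosystems produce, but temperature
rarely acts alone: resource supply usually covaries with it. Metabolic
scaling theory predicts that once resource supply is held fixed, community
secondary production should be *independent* of temperature — biomass and
biomass turnover respond in opposite directions and cancel. Testing that
prediction requires a full estimation chain: size-structured benthic samples
→ biomass, growth incubations → mass-specific growth rates, the two combined
into production with honest uncertainty, production regressed against a
temperature axis on which slopes are activation energies, and finally a
model competition asking whether temperature explains anything once
resources (chlorophyll *a*, gross primary production) are in the model.

`streamprod` implements that chain for multi-stream study designs (e.g.
geothermally heated stream networks spanning ~5–28 °C), plus a seeded
synthetic-data generator with known ground truth so every estimator is
testable without field data.

## The core quantities

- Instantaneous growth: `g = ln(W_{t+Δt}/W_t)/Δt` (d⁻¹).
- Interval production: `P = g·Δt·(B_t + B_{t+Δt})/2` (mg AFDM m⁻²), summed
  over size classes, populations, intervals — replicate-wise through a
  paired bootstrap, so community P is exactly the sum of population P and
  P:B × B returns P.
- Standardised Boltzmann temperature: `x(T) = 1/(k·T₁₅) − 1/(k·T)` with
  `k = 8.62×10⁻⁵ eV K⁻¹`; the OLS slope of ln(quantity) on x is an apparent
  activation energy E (eV).
- Mass-corrected B and P:B (community body-mass effect M_c^±0.25 removed)
  give E_b and E_pb whose sum with E_p is exact per bootstrap replicate.
- Resource correction: among streams, the temperature coefficient of the
  additive `ln P ~ x + ln chla` model; within streams, E_p − E_gpp from a
  mixed-model competition with random stream intercepts.

## Worked example

```python
from streamprod import SimulationConfig, simulate_study
from streamprod.io import StudyConfig, run_pipeline

study = simulate_study(SimulationConfig(seed=42), out_dir="demo_study")
cfg = StudyConfig(input_dir="demo_study", out_dir="demo_results", seed=7,
                  n_boot_production=500, n_boot_slopes=2000, n_rep_selection=300)
result = run_pipeline(cfg)

for s, p in result.annual_production.items():
    print(f"{s}: P = {p.mean:6.2f} g AFDM m^-2 y^-1  (95% CI {p.ci_low:.2f}-{p.ci_high:.2f})")
e_p = result.activation_energies[0]
print(f"E_p_among = {e_p.E_mean:.2f} eV (95% CI {e_p.ci_low:.2f}-{e_p.ci_high:.2f}), r2 = {e_p.r2:.2f}")
sel = result.among_selection
print(f"top model: {sel.winner} ({100*sel.frequencies[sel.winner]:.0f}% of replicates)")
ce = sel.corrected_E
print(f"resource-corrected E = {ce.mean:.2f} eV (95% CI {ce.ci_low:.2f}-{ce.ci_high:.2f})")
```

prints

```
st1: P =   1.08 g AFDM m^-2 y^-1  (95% CI 0.92-1.22)
st2: P =   2.37 g AFDM m^-2 y^-1  (95% CI 2.07-2.71)
st3: P =   1.06 g AFDM m^-2 y^-1  (95% CI 0.91-1.21)
st4: P =   0.68 g AFDM m^-2 y^-1  (95% CI 0.60-0.77)
st5: P =   2.39 g AFDM m^-2 y^-1  (95% CI 2.06-2.75)
st6: P =   8.30 g AFDM m^-2 y^-1  (95% CI 7.17-9.41)
E_p_among = 0.55 eV (95% CI 0.50-0.60), r2 = 0.59
top model: chla (100% of replicates)
resource-corrected E = -0.02 eV (95% CI -0.24-0.14)
```

Reading this: annual production rises with temperature among the six
simulated streams (apparent E ≈ 0.55 eV — roughly +9 % per °C), but the
chlorophyll-only model wins the AICc competition in every bootstrap
replicate, and after accounting for chlorophyll the temperature coefficient
straddles zero: production was generated with *no* direct temperature
effect, and the pipeline recovers exactly that.

The same run is available from the shell:

```sh
streamprod simulate --out demo_study --seed 42
streamprod run --input-dir demo_study --out demo_results --seed 7
```

Outputs are CSV (`production_intervals.csv`, `production_annual.csv`,
`activation_energies.csv`, `selection_report.csv`, `corrected_E.csv`) plus a
`manifest.json` recording seed, bootstrap sizes and config hash; re-running
with the same inputs and seed reproduces every file byte for byte.

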