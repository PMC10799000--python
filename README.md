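# dryq10

Source-partitioned temperature sensitivity of soil CO2 emissions in
drylands: isotope partitioning, Q10 estimation, aridity-gradient
statistics, path modelling, and carbon-budget upscaling — with a
synthetic-cohort generator so the whole chain is verifiable end to end.

## The problem

Dryland soils hold carbon in two very different pools: soil organic carbon
(SOC), respired by microbes, and soil inorganic carbon (SIC, pedogenic
carbonate), released by dissolution. Both emit CO2, but with different
temperature sensitivities, and warming projections that treat all soil CO2
as "SOC-like" mis-state the carbonate contribution. Because organic matter
is strongly depleted in ¹³C (δ¹³C near −24‰ VPDB) while carbonate sits near
−2‰, the δ¹³C of emitted CO2 identifies the source mix.

`dryq10` implements the full analysis chain for closed-jar incubation
experiments along an aridity gradient:

1. **Headspace flux** — emission rates from CO2 accumulation in a sealed,
   CO2-free-flushed jar: `rate = ΔC·V_head/V_m(T)·M_C/(m_soil·Δt)` in
   μg C g⁻¹ h⁻¹, with the ideal-gas molar volume at jar temperature.
2. **Isotope partitioning** — the two-end-member mixing model
   `δ¹³C_total = (1−f_SIC)·δ¹³C_SOC + f_SIC·δ¹³C_SIC`, after correcting the
   emitted δ¹³C for diffusive fractionation (emitted CO2 is 4.4‰ lighter
   than soil CO2). `f_SIC` splits each total rate into SOC- and SIC-derived
   components, conserving the total exactly.
3. **Q10 fitting** — per sample and source, `R = B·e^{kT}` over the
   5–30 °C ramp by log-linear least squares; `Q10 = e^{10k}`. Fits are
   gated by R² > 0.95 (SOC, total) or R² > 0.85 (SIC) and ≥4 positive
   points.
4. **Gradient statistics** — OLS of field-moisture Q10s on the aridity
   index (AI = precipitation / potential evapotranspiration), two-sided
   paired t tests between water-holding-capacity (WHC) treatments, and a
   Pearson screen of Q10 against climate, physical, chemical and substrate
   factors with optional Holm correction.
5. **Path model** — each factor group is collapsed to the first principal
   component of its standardized members; a recursive system of structural
   equations (least squares per equation, maximum-likelihood-equivalent for
   recursive observed systems) yields standardized direct, indirect and
   total effects plus χ²/RMSEA/GFI fit indices.
6. **Upscaling** — the dryland carbon bookkeeping: heterotrophic
   respiration, warming-induced SIC-derived fluxes under alternative Q10s
   (`ΔF = F·(Q10^{ΔT/10} − 1)`), and the offset between the SOC-flux
   decline and SIC-flux rise per 0.1 decrease in aridity index.

A synthetic cohort generator (`dryq10.synthetic`) emulates the study
design — 30 sites spanning AI 0.04–0.59, two depths, four moisture
conditions, six-temperature incubation series — with known ground-truth
Q10s, so parameter recovery, calibration and directional results can all be
tested without any field data.

## Worked example

```python
from dryq10 import GeneratorConfig, RunConfig, generate_cohort
from dryq10.pipeline import q10_table, q10_wide, gradient_analysis

cfg = RunConfig(seed=1, generator=GeneratorConfig(seed=1))
cohort = generate_cohort(cfg.generator)           # sites, samples, gas series
fits = q10_table(cohort, cfg)                     # flux -> partition -> Q10
wide = q10_wide(fits, cohort.sites)
print(gradient_analysis(wide).round(3).to_string(index=False))
```

```
  depth source  slope  slope_per_0p1_ai  intercept      r  p_value  ci95_low  ci95_high  n
subsoil    SOC  4.620             0.462      1.645  0.924      0.0     3.880      5.360 30
subsoil    SIC -4.026            -0.403      5.321 -0.949      0.0    -4.543     -3.509 30
topsoil    SOC  4.597             0.460      1.717  0.941      0.0     3.957      5.237 30
topsoil    SIC -4.988            -0.499      5.944 -0.918      0.0    -5.824     -4.153 30
```

Q10 of SOC-derived CO2 *increases* with aridity index (≈ +0.46 per 0.1 AI,
i.e. it falls as sites get drier), while Q10 of SIC-derived CO2 moves the
opposite way — the generator's built-in gradient (+0.47 / −0.39 per 0.1 AI)
recovered through the full measurement-and-inversion chain.

The carbon-budget arithmetic, from the command line:

```bash
$ dryq10 upscale
{
  "dryland_het_resp": 20.3808,
  "f_sic_base": 5.502816,
  "warming_flux_soc_q10": 3.193931291216618,
  "warming_flux_sic_q10": 4.294816339084587,
  "underestimate_pct": 25.63287835732263,
  "soc_reduction": 1.4766247291454473,
  "sic_gain": 0.3518006750243323,
  "offset_pct": 26.666666666666668,
  "offset_pct_full": 23.824650101039992,
  ...
}
```

Dryland heterotrophic respiration is 20.4 Pg C yr⁻¹; under 4 °C of warming
its SIC-derived share would rise by 3.2 Pg C yr⁻¹ if given the SOC Q10 but
by 4.3 Pg C yr⁻¹ at the higher SIC Q10 — a 25.6% underestimate. Per 0.1
decrease in aridity index, the SOC-flux decline (1.5 Pg C yr⁻¹) is offset
by ≈26.7% by the SIC-flux gain (0.4 Pg C yr⁻¹; printed-rounding mode —
`offset_pct_full` keeps full precision).

Other entry points: `dryq10 simulate|flux|partition|q10|gradient|pathmodel|all`
(see `dryq10 --help`), or `dryq10.pipeline.run_all(config, out_dir)` to run
every stage and write all CSV/JSON outputs.

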