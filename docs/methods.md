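# Methods

This note documents the models, conventions and design choices behind
`dryq10`, in the order the pipeline runs. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Closed-jar flux computation

Each temperature step of the ramp is a closed-chamber accumulation
experiment: the jar is sealed, flushed with CO2-free air, and headspace CO2
is measured at the start and after the step duration. The emission rate is

    rate = ΔC × 10⁻⁶ × V_head / V_m(T) × M_C × 10⁶ / (m_soil × Δt)

in μg C g⁻¹ (dry soil) h⁻¹, with ΔC the concentration change (ppm), V_head
the headspace volume (L), M_C = 12.011 g mol⁻¹, and the ideal-gas molar
volume V_m(T) = 22.414 × (T + 273.15)/273.15 L mol⁻¹ at 1 atm. Using the
molar volume at jar temperature and 1 atm is the standard chamber
convention; pressure is a config field but no further gas-law refinement is
attempted.

The headspace volume is the jar volume minus soil mass over an assumed bulk
density (default 1.3 g cm⁻³). The density is a config parameter rather than
a measured porosity: it keeps the geometry auditable, and the rate depends
on it only through a multiplicative constant that cancels from Q10 (a ratio
of rates).

The initial 15 mL headspace sample and its replacement by CO2-free air are
represented in the protocol but have no effect on the accumulation when
jars are flushed: the gas removed and the gas injected both contain
(essentially) no CO2. The rate inversion is therefore an exact two-point
difference, and negative measured rates are retained with a QC flag rather
than clipped — they are excluded later by the fit's positive-point rule.

## Isotope partitioning

The two-end-member mixing model is linear in δ units:

    δ_total = (1 − f_SIC)·δ_SOC + f_SIC·δ_SIC  ⇒  f_SIC = (δ_total − δ_SOC)/(δ_SIC − δ_SOC)

Working in δ rather than isotope-ratio space is an approximation, but with
end members ~22‰ apart the curvature error is negligible against
measurement noise. Two corrections precede the inversion:

* **Diffusion offset** (default +4.4‰): emitted CO2 is lighter than soil
  CO2 because of molecular-diffusion fractionation; the offset is added to
  the emitted δ¹³C to recover soil CO2.
* **Temperature fractionation** of the end members, as a linear hook
  δ + a + b·T with default (0, 0): the default assumes source and
  source-derived CO2 share one δ¹³C value. Any non-trivial correction is
  opt-in config, since no specific functional form is canonical.

Fractions outside [0, 1] (noise excursions past an end member) are clamped
to the nearest bound and flagged, which preserves conservation while
keeping the excursions auditable. End members closer than 5‰ (config) raise
an error: below that separation the inversion variance explodes. The split
into components re-derives one component from the other wherever the
floating-point sum would miss the total by an ulp, so
r_SOC + r_SIC == rate_total holds bit-exactly on every record.

## Q10 estimation

Rates follow R = B·e^{kT} over the whole 5–30 °C ramp (a single k; no
piecewise Q10), and Q10 = e^{10k}. The default estimator is ordinary least
squares on ln R vs T: it is closed-form, deterministic, and exact in the
noiseless limit. Nonlinear least squares on the raw scale is available
(`method="nls"`, initialised from the OLS fit) as a sensitivity check; R²
is always that of the log-linear regression so the QC gate does not depend
on the estimator.

QC: a fit needs at least 4 strictly positive rate points (of 6 nominal
temperatures, preserving ≥2 residual degrees of freedom) and R² above 0.95
for SOC-derived (and total) CO2 or 0.85 for SIC-derived CO2. Failures are
reported with a reason and excluded from downstream statistics, not
imputed. Substrate indices: CAI = basal/substrate-induced respiration;
D_SOC = fitted B of the SOC source per unit SOC content; SIC from carbonate
content × 0.12 (the carbon mass fraction of CaCO3).

## Gradient statistics

Aridity regressions use per-site field-moisture Q10s only; WHC treatments
feed only the paired tests. Slopes are reported both per unit AI and per
0.1 AI (the scale on which aridity scenarios are usually phrased). Paired
comparisons are classical two-sided paired t tests by site; zero-variance
differences are flagged degenerate rather than producing NaNs. The factor
screen is Pearson correlation with Holm correction within each response row
(default on, config off): the correction family is a documented choice, as
no specific procedure is canonical for such screens.

## Path model

Each factor group — climate (MAT, AI), physical (OC-MAOM, OC-Fe, OC-Ca,
OC-POM), chemical (pH, CEC, Ca²⁺, Mg²⁺), substrate (SOC, SIC, CAI,
D_SOC) — is collapsed to the first principal component of its standardized
members. The eigenvector sign is fixed by requiring a positive loading for
the first listed member; the physical group lists OC-MAOM first so the
composite is oriented toward mineral protection (a "physicochemical
protection" axis), which makes its path coefficients directly
interpretable against the protection hypothesis.

The default DAG is: climate → each of {physical, chemical, substrate}, and
all four composites → response, with no edges among the three soil groups.
The exact inter-group topology of such models is a modelling choice; the
DAG is config (YAML edge list) so any recursive structure can be fitted.
Each structural equation is estimated by least squares on standardized
variables — identical to maximum likelihood for a recursive, fully observed
system — so the standardized coefficients are ML path coefficients without
iterative optimisation. Effects decompose as direct (the edge into the
response), indirect (sum over all other directed paths of coefficient
products, computed as (I−B)⁻¹ − I), and total = direct + indirect, exactly.

Fit indices use the ML discrepancy F = ln|Σ̂| + tr(SΣ̂⁻¹) − ln|S| − p with
χ² = (n−1)F, df = p(p+1)/2 minus free parameters (edges, residual
variances, exogenous (co)variances), RMSEA = √(max(0, χ²−df)/(df(n−1)))
(zero at df = 0), and the standard ML GFI. The default DAG omits
covariances among the three soil-group residuals, so on realistic data it
is expected to show misfit (χ² ≫ df); the indices report this honestly
rather than being minimised away.

## Synthetic cohort generator

The generator emulates the study design: `n_sites` = 30 sites spanning
AI 0.04–0.59, MAT −1.2–10.0 °C drawn independently of AI, MAP linear in AI
(46–486 mm), soils at two depths, incubated at field moisture and at
20/40/60% WHC, six temperatures per jar. AI values are evenly spaced plus a
small jitter — a deliberate transect design rather than i.i.d. sampling —
so every cohort spans the gradient and slope recovery is stable.

Ground truth, per site × depth × moisture and source:

    Q10 = mean + slope × (AI − cohort-mean AI) [+ whc_effect × (level − 1)] + N(0, 0.25)

with means 3.14 (SOC) and 4.23 (SIC) — chosen so that carrying the cohort
means into the warming arithmetic reproduces the budget chain — slopes
+4.7 / −3.9 per unit AI, and WHC effects ±0.4 per treatment step (opposite
signs for the two sources, centred on WHC40; field moisture carries no WHC
term). The same slopes apply in both depths. The moisture effect size is
set so paired tests at n = 30 are decisive without being trivial.

Rates are calibrated at 20 °C: the SOC-derived rate is 1.0 (topsoil) or
0.3 (subsoil) μg C g⁻¹ h⁻¹ times a per-soil log-normal factor (SD 0.5 on
the log scale — across-site respiration rates realistically span several
fold) and a moisture factor (drier jars emit less); B = r(20)/e^{20k}. The
SIC-derived 20 °C rate is fixed at r_SOC(20)·c/(1−c) with c = 0.072
(topsoil) / 0.111 (subsoil), so the partitioned f_SIC at 20 °C is exactly
c before noise.

Soil properties are linear-in-AI trends plus noise, signed to the field's
qualitative structure: pH, CEC, Ca²⁺, Mg²⁺, SIC and the mineral-bound
organic fractions rise toward the arid end; total SOC, particulate organic
matter and CAI rise toward the wetter end. Two noise layers are used:
idiosyncratic per-property noise, and a *group-level* latent deviation
shared by the members of each property group (chemical / physical /
substrate), emulating parent-material and site-history variation that
moves a soil's whole chemistry coherently off the climate trend. The group
deviations are what keep the PCA composites strong (members correlate
within groups) yet not collinear proxies of AI — without them all four
composites collapse onto the aridity axis and path coefficients at n = 30
are unidentifiable in practice. The substrate deviation enters SOC and SIC
with opposite signs (organic-rich deviations pair with carbonate-poor
soils). Magnitudes were chosen so each composite correlates with AI at
roughly |r| ≈ 0.7–0.8; at that strength the directional path results are
stable for the large majority of seeds, though individual cohorts can
still produce a near-zero chemical effect — a genuine small-sample
property of path analysis on 30 sites, not a defect of the estimator.

δ¹³C end members are drawn per soil at N(−24, 1)‰ (organic) and N(−2, 1)‰
(carbonate) — literature-typical values kept well separated; they are
config, not claims. Measurement noise defaults: 5 ppm on concentrations
and 0.1‰ on δ¹³C (cavity-ring-down instrument class). Headspace series are
forward-computed with exactly the conventions the inversion applies, so
with measurement noise off the full pipeline reproduces every ground-truth
Q10 to machine precision (the round-trip tests assert ≤1e−6 relative
error; observed errors are ~1e−15).

Every stage draws from a named substream (`SeedSequence.spawn`) of the
master seed: identical seeds give bit-identical cohorts, and stages can be
re-run in isolation.

### What the generator does not emulate

No spatial autocorrelation or geostatistical realism; no soil-profile
physics linking depths; no microbial community dynamics or substrate
depletion over the ramp; no carbonate-system speciation (the dissolution
chemistry is background, not simulated). Passing tests therefore show that
the *statistical machinery* recovers known structure under the study's
design and realistic noise — not that the structure holds in real soils.

## Upscaling arithmetic

Constants: global soil respiration 88.0 Pg C yr⁻¹, dryland share 38.6%,
heterotrophic fraction 60% (product: 20.4 Pg C yr⁻¹), SIC share 27%,
warming 4 °C. The warming increment uses ΔF = F·(Q10^{ΔT/10} − 1); the
mean Q10s (3.14 / 4.23) and the budget total are back-calculations against
this declared form — solving F·(Q10^{0.4} − 1) for the printed fluxes —
since budget narratives of this kind typically publish the numbers but not
the formula. The aridity-offset step shifts the SOC Q10 down by 0.47 and
the SIC Q10 up by 0.39 (per 0.1 AI decrease) and differences the warming
increments. In the default "printed" rounding mode both components are
rounded to one decimal before the offset ratio (0.4/1.5 → 26.7%),
matching how chained budget numbers are conventionally reported from
rounded intermediates; "full" mode keeps full precision and yields ≈24%.
Both are always reported.

## Numerical choices and degenerate inputs

* Log-OLS fit refusal below 4 positive points, flat series flagged (Q10 = 1,
  R² undefined → QC fail).
* Zero-variance regressors/responses: AI without variance is an error; a
  constant response regresses to slope 0, r 0.
* Paired tests with zero-variance differences are flagged degenerate (t = 0,
  p = 1 when all differences vanish).
* Constant factor columns in the correlation screen yield flagged NaN cells
  rather than exceptions; constant composite members are errors naming the
  column.
* Config blocks reject unknown keys and round-trip losslessly through YAML.

## Problem sizes

Defaults throughout are the study's own dimensions: 30 sites × 2 depths ×
4 moisture conditions × 6 temperatures. Monte-Carlo checks use 200 cohorts
for slope recovery, 100 for structural sign frequencies, 1000–2000
replicates for estimator bias and type-I-error calibration — sizes at
which the Monte-Carlo standard errors are comfortably below the asserted
tolerances.

## Known limitations

* The linear-in-δ mixing model and the constant diffusion offset are
  conventions; systematic errors in either bias f_SIC multiplicatively and
  are not separately identifiable from one incubation.
* Q10 summarises the whole 5–30 °C ramp with one exponent; curvature
  (e.g. Arrhenius-type) is out of scope.
* The path model is observed-variable only (no latent measurement models,
  modification indices, or bootstrap standard errors), and its default DAG
  is one defensible topology among several.
* The upscaling is global bookkeeping arithmetic, not spatial upscaling;
  uncertainty propagation beyond the two rounding conventions is left to
  config sweeps.
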