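"""Synthetic dryland cohort with known ground truth.

Emulates a two-experiment incubation study on a dryland transect: ``n_sites``
sites spanning the configured aridity-index (AI) range, soils from two
depths, incubated at field moisture (aridity-gradient experiment) and at
20/40/60% water-holding capacity (moisture-control experiment).  Each
sample's SOC- and SIC-derived CO2 rates follow R = B exp(kT) with ground
truth Q10s that are linear in AI (opposite slopes for the two sources),
shifted linearly by WHC treatment, plus Gaussian site noise.  Headspace CO2
accumulation and its delta13C are forward-computed with exactly the
conventions the analysis pipeline inverts, so with measurement noise off the
round trip is exact.

Site AI values are evenly spaced across the range plus a small jitter —
mimicking a deliberate transect design — so every cohort spans the full
gradient.  Soil properties are linear-in-AI trends plus independent Gaussian
noise, signed to reproduce the field's qualitative structure: pH, SIC,
exchangeable Ca/Mg, CEC and mineral-bound organic fractions all increase
toward the arid end (low AI), while total SOC, particulate organic matter
and the carbon availability index increase toward the wetter end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    MOLAR_MASS_C,
    WHC_INDEX,
    EndMembers,
    GeneratorConfig,
    IncubationProtocol,
)
from .gas_flux import headspace_volume, molar_volume
from .isotope import correct_temperature_fractionation

#: Relative emission-rate multiplier per moisture treatment (drier soils emit
#: less; field moisture is the reference condition of the gradient experiment).
MOISTURE_RATE_FACTOR = {"field": 1.0, "WHC20": 0.7, "WHC40": 0.85, "WHC60": 1.0}

# Linear-in-AI soil property trends:
# name -> (intercept, AI slope, idiosyncratic SD, floor, group, group coefficient).
# Each property group (chemical / physical / substrate) shares a per-soil
# latent deviation (parent-material-like site variation), so group members
# move coherently off the aridity trend and the PCA composites are strong
# but not collinear proxies of AI.
_SOIL_TRENDS_COMMON = {
    "ph": (8.8, -2.0, 0.15, 4.0, "chem", 0.18),
    "cec": (12.0, -6.0, 0.80, 0.5, "chem", 0.55),
    "ca": (3.0, -3.0, 0.30, 0.05, "chem", 0.27),
    "mg": (1.5, -1.5, 0.15, 0.02, "chem", 0.13),
    "sic": (12.0, -14.0, 2.00, 0.1, "subs", -2.00),
    "oc_pom": (0.5, 4.0, 0.30, 0.02, "phys", -0.25),
    "oc_maom": (4.0, -3.5, 0.25, 0.05, "phys", 0.35),
    "oc_fe": (1.5, -1.5, 0.12, 0.02, "phys", 0.15),
    "oc_ca": (1.2, -1.2, 0.10, 0.02, "phys", 0.13),
    "basal_resp": (0.12, 0.30, 0.03, 0.01, "subs", 0.05),
    "sir_resp": (1.2, 0.0, 0.10, 0.2, None, 0.0),
}
# SOC by depth: (intercept, AI slope, idiosyncratic SD, floor, substrate-group coef)
_SOC_TRENDS = {"topsoil": (4.0, 18.0, 1.5, 0.3, 2.5), "subsoil": (2.0, 9.0, 0.8, 0.15, 1.3)}


@dataclass
class Cohort:
    sites: pd.DataFrame
    samples: pd.DataFrame
    incubation: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(out / "sites.csv", index=False)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.incubation.to_csv(out / "incubation.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _rngs(seed: int) -> dict:
    """Named substreams so each stage is reproducible in isolation."""
    names = ("sites", "soils", "q10", "incubation")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_sites(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.ai_range
    n = config.n_sites
    base = np.linspace(lo, hi, n)
    spacing = (hi - lo) / max(n - 1, 1)
    ai = np.clip(base + rng.uniform(-0.3, 0.3, n) * spacing, lo, hi)
    mat = rng.uniform(config.mat_range[0], config.mat_range[1], n)  # independent of AI
    m_lo, m_hi = config.map_range
    map_mm = np.clip(
        m_lo + (m_hi - m_lo) * (ai - lo) / (hi - lo) + rng.normal(0, 20, n), 5.0, None)
    return pd.DataFrame({
        "site_id": [f"site{i + 1:02d}" for i in range(n)],
        "aridity_index": ai,
        "mat": mat,
        "map": map_mm,
        "longitude": np.linspace(81.0, 123.5, n),
    })


def generate_soils(
    config: GeneratorConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """One soil record per site x depth (properties shared across moistures)."""
    rows = []
    for depth in config.depths:
        df = sites[["site_id", "aridity_index"]].copy()
        df["depth"] = depth
        ai = df["aridity_index"].to_numpy()
        n = len(df)
        group_dev = {g: rng.normal(0, 1, n) for g in ("chem", "phys", "subs")}
        for name, (b0, b1, sd, floor, group, gcoef) in _SOIL_TRENDS_COMMON.items():
            dev = gcoef * group_dev[group] if group else 0.0
            df[name] = np.clip(
                b0 + b1 * ai + dev + rng.normal(0, sd, n), floor, None)
        b0, b1, sd, floor, gcoef = _SOC_TRENDS[depth]
        df["soc"] = np.clip(
            b0 + b1 * ai + gcoef * group_dev["subs"] + rng.normal(0, sd, n),
            floor, None)
        df["ph"] = np.clip(df["ph"], 4.0, 11.0)
        df["delta13c_soc"] = rng.normal(
            config.delta13c_soc_mean, config.delta13c_soc_sd, n)
        df["delta13c_sic"] = rng.normal(
            config.delta13c_sic_mean, config.delta13c_sic_sd, n)
        # per-soil spread of the reference 20 degC SOC-derived rate
        r20 = config.r_soc_20c_topsoil if depth == "topsoil" else config.r_soc_20c_subsoil
        df["r_soc_20c"] = r20 * np.exp(rng.normal(0, config.rate_lognorm_sd, n))
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_truth(
    config: GeneratorConfig, soils: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Ground-truth Q10s and rate parameters per site x depth x moisture.

    Field moisture carries the aridity-gradient structure
    (mean + slope * centred AI + noise); WHC treatments add the linear
    moisture effect with opposite signs for the two sources.
    """
    ai_c = soils["aridity_index"] - soils["aridity_index"].mean()
    depth_idx = {"topsoil": 0, "subsoil": 1}
    rows = []
    for moisture in config.moisture_levels:
        df = soils[["site_id", "depth", "aridity_index", "r_soc_20c"]].copy()
        df["moisture"] = moisture
        whc = 0.0 if moisture == "field" else WHC_INDEX[moisture] - 1
        n = len(df)
        q10_soc = (config.q10_soc_mean + config.q10_soc_slope * ai_c.to_numpy()
                   + config.whc_effect_soc * whc
                   + rng.normal(0, config.q10_noise_sd, n))
        q10_sic = (config.q10_sic_mean + config.q10_sic_slope * ai_c.to_numpy()
                   + config.whc_effect_sic * whc
                   + rng.normal(0, config.q10_noise_sd, n))
        df["true_q10_soc"] = np.maximum(q10_soc, config.q10_floor)
        df["true_q10_sic"] = np.maximum(q10_sic, config.q10_floor)
        rows.append(df)
    truth = pd.concat(rows, ignore_index=True)
    truth["sample_id"] = (
        truth["site_id"].str.replace("site", "S", regex=False)
        + "_" + truth["depth"] + "_" + truth["moisture"])
    truth["true_k_soc"] = np.log(truth["true_q10_soc"]) / 10.0
    truth["true_k_sic"] = np.log(truth["true_q10_sic"]) / 10.0
    factor = truth["moisture"].map(MOISTURE_RATE_FACTOR).to_numpy()
    r20_soc = truth["r_soc_20c"].to_numpy() * factor
    c = np.array([config.sic_contribution_20c[depth_idx[d]] for d in truth["depth"]])
    r20_sic = r20_soc * c / (1.0 - c)  # calibrates f_SIC at 20 degC to c
    truth["true_b_soc"] = r20_soc / np.exp(20.0 * truth["true_k_soc"])
    truth["true_b_sic"] = r20_sic / np.exp(20.0 * truth["true_k_sic"])
    truth["true_f_sic_20c"] = c
    cols = ["sample_id", "site_id", "depth", "moisture", "aridity_index",
            "true_q10_soc", "true_q10_sic", "true_k_soc", "true_k_sic",
            "true_b_soc", "true_b_sic", "true_f_sic_20c"]
    return truth[cols]


def source_rates(truth_row, temperature):
    """Forward source rates (r_soc, r_sic) in ug C g-1 h-1 at a temperature.

    ``truth_row`` is any mapping with true_b_soc/true_k_soc/true_b_sic/
    true_k_sic ground-truth parameters.
    """
    try:
        r_soc = truth_row["true_b_soc"] * np.exp(truth_row["true_k_soc"] * temperature)
        r_sic = truth_row["true_b_sic"] * np.exp(truth_row["true_k_sic"] * temperature)
    except KeyError as e:
        raise ValueError(f"ground-truth parameter missing: {e}") from e
    return r_soc, r_sic


def synthesize_incubation(
    truth: pd.DataFrame,
    samples: pd.DataFrame,
    protocol: IncubationProtocol,
    ends: EndMembers,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Forward-compute the headspace gas series for every sample.

    For each temperature step the jar is flushed to ~0 ppm, CO2 accumulates
    from the two source rates over the step duration, and the headspace
    delta13C is the source mixture shifted down by the diffusion offset —
    the same conventions the inversion applies, so the noiseless round trip
    is exact.  The initial 15 mL headspace sampling is CO2-free gas and its
    replacement is CO2-free air, so it does not perturb the accumulation.
    Measurement noise (ppm on concentrations, permil on delta13C) is added
    last.
    """
    protocol.validate()
    if any(d <= 0 for d in protocol.step_durations_h):
        raise ValueError("step durations must be positive")
    merged = truth.merge(
        samples[["sample_id", "delta13c_soc", "delta13c_sic"]], on="sample_id")
    n_steps = len(protocol.temperatures_c)
    rep = merged.loc[merged.index.repeat(n_steps)].reset_index(drop=True)
    t = np.tile(np.asarray(protocol.temperatures_c, float), len(merged))
    dur = np.tile(np.asarray(protocol.step_durations_h, float), len(merged))

    r_soc, r_sic = source_rates(rep, t)
    r_tot = r_soc + r_sic
    with np.errstate(invalid="ignore"):
        f = np.where(r_tot > 0, r_sic / np.where(r_tot > 0, r_tot, 1.0), 0.0)
    d_soc = correct_temperature_fractionation(
        rep["delta13c_soc"].to_numpy(), t, ends.temp_frac_a, ends.temp_frac_b)
    d_sic = correct_temperature_fractionation(
        rep["delta13c_sic"].to_numpy(), t, ends.temp_frac_a, ends.temp_frac_b)
    delta_soil = (1.0 - f) * d_soc + f * d_sic
    delta_head = delta_soil - ends.diffusion_offset

    v_head = headspace_volume(protocol)
    v_m = molar_volume(t, protocol.pressure_atm)
    acc_ppm = (r_tot * protocol.soil_mass_g * dur * v_m
               / (MOLAR_MASS_C * v_head))

    n = len(rep)
    co2_initial = np.zeros(n)
    co2_final = acc_ppm.astype(float)
    if config.co2_noise_sd_ppm > 0:
        co2_initial = np.maximum(
            0.0, rng.normal(0, config.co2_noise_sd_ppm, n))
        co2_final = np.maximum(
            0.0, co2_final + rng.normal(0, config.co2_noise_sd_ppm, n))
    if config.delta13c_noise_sd > 0:
        delta_head = delta_head + rng.normal(0, config.delta13c_noise_sd, n)

    return pd.DataFrame({
        "sample_id": rep["sample_id"],
        "temperature_C": t,
        "duration_h": dur,
        "co2_initial_ppm": co2_initial,
        "co2_final_ppm": co2_final,
        "delta13c_headspace_permil": delta_head,
    })


def generate_cohort(
    config: GeneratorConfig,
    protocol: IncubationProtocol | None = None,
    ends: EndMembers | None = None,
) -> Cohort:
    """Generate a full synthetic study: sites, samples, gas series, truth.

    Deterministic given ``config.seed``; each stage draws from a named
    substream of the master seed.
    """
    config.validate()
    protocol = (protocol or IncubationProtocol()).validate()
    ends = (ends or EndMembers()).validate()
    rngs = _rngs(config.seed)
    sites = generate_sites(config, rngs["sites"])
    soils = generate_soils(config, sites, rngs["soils"])
    truth = generate_truth(config, soils, rngs["q10"])

    # analysis-facing sample table: soil properties replicated per moisture,
    # without ground-truth columns
    samples = truth[["sample_id", "site_id", "depth", "moisture"]].merge(
        soils.drop(columns=["r_soc_20c", "aridity_index"]),
        on=["site_id", "depth"])
    prop_cols = ["ph", "cec", "ca", "mg", "soc", "sic", "oc_pom", "oc_maom",
                 "oc_fe", "oc_ca", "basal_resp", "sir_resp",
                 "delta13c_soc", "delta13c_sic"]
    samples = samples[["sample_id", "site_id", "depth", "moisture"] + prop_cols]

    incubation = synthesize_incubation(
        truth, samples, protocol, ends, rngs["incubation"], config)
    return Cohort(sites=sites, samples=samples, incubation=incubation, truth=truth)
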