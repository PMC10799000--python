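"""Table schemas, validation, and the end-to-end analysis pipeline.

Stages: simulate (or load) -> headspace flux -> isotope partition -> Q10
fits -> aridity-gradient statistics -> path model -> upscaling.  All tables
are plain UTF-8 CSV with a header row; missing values are empty cells.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gas_flux, gradient, isotope, pathmodel, q10 as q10mod, upscaling
from .config import RunConfig, WHC_INDEX
from .synthetic import Cohort, generate_cohort

log = logging.getLogger("dryq10")

SCHEMAS = {
    "sites.csv": ["site_id", "aridity_index", "mat", "map"],
    "samples.csv": [
        "sample_id", "site_id", "depth", "moisture", "ph", "cec", "ca", "mg",
        "soc", "sic", "oc_pom", "oc_maom", "oc_fe", "oc_ca",
        "basal_resp", "sir_resp", "delta13c_soc", "delta13c_sic",
    ],
    "incubation.csv": [
        "sample_id", "temperature_C", "duration_h",
        "co2_initial_ppm", "co2_final_ppm", "delta13c_headspace_permil",
    ],
}
_NON_NUMERIC = {"site_id", "sample_id", "depth", "moisture"}

FACTOR_COLUMNS = ["mat", "aridity_index", "oc_ca", "oc_fe", "oc_pom", "oc_maom",
                  "ph", "cec", "ca", "mg", "soc", "sic", "cai", "d_soc"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _validate(df: pd.DataFrame, name: str) -> pd.DataFrame:
    required = SCHEMAS[name]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing column {col!r}")
    if name == "incubation.csv" and df.empty:
        raise SchemaError("no incubation records")
    for col in required:
        if col in _NON_NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{name}: non-numeric value {df.loc[row, col]!r} "
                f"in column {col!r}, row {row}")
        df[col] = coerced
    if name == "samples.csv" and df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"samples.csv: duplicate sample_id {dup!r}")
    return df


def read_tables(in_dir) -> Cohort:
    """Load and schema-validate a study directory (sites/samples/incubation).

    A truth.csv, if present (synthetic cohorts), is carried along.
    """
    in_dir = Path(in_dir)
    frames = {}
    for name in SCHEMAS:
        path = in_dir / name
        if not path.exists():
            raise SchemaError(f"required table {name} not found in {in_dir}")
        frames[name] = _validate(pd.read_csv(path), name)
    truth_path = in_dir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    log.info("loaded %d sites, %d samples, %d incubation steps",
             len(frames["sites.csv"]), len(frames["samples.csv"]),
             len(frames["incubation.csv"]))
    return Cohort(sites=frames["sites.csv"], samples=frames["samples.csv"],
                  incubation=frames["incubation.csv"], truth=truth)


def q10_table(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    """Flux -> partition -> per-sample Q10 fits, with sample metadata attached."""
    rates = gas_flux.emission_rates(cohort.incubation, config.protocol)
    part = isotope.partition_table(rates, cohort.samples, config.end_members)
    fits = q10mod.fit_cohort(part, qc=config.qc)
    meta = cohort.samples[["sample_id", "site_id", "depth", "moisture"]]
    return fits.merge(meta, on="sample_id", validate="many_to_one")


def partition_at(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    rates = gas_flux.emission_rates(cohort.incubation, config.protocol)
    return isotope.partition_table(rates, cohort.samples, config.end_members)


def q10_wide(fits: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Pivot fits to one row per sample with q10_soc / q10_sic / q10_total.

    QC-failed fits become NaN so downstream analyses drop them pairwise.
    """
    f = fits.copy()
    f.loc[~f["qc_pass"].astype(bool), "q10"] = np.nan
    wide = f.pivot_table(
        index=["sample_id", "site_id", "depth", "moisture"],
        columns="source", values="q10", aggfunc="first").reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"SOC": "q10_soc", "SIC": "q10_sic",
                                "total": "q10_total"})
    b_soc = f[(f["source"] == "SOC")][["sample_id", "B"]].rename(
        columns={"B": "b_soc"})
    wide = wide.merge(b_soc, on="sample_id", how="left")
    return wide.merge(sites[["site_id", "aridity_index", "mat"]], on="site_id")


def build_factors(wide: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample factor table (climate, physical, chemical, substrate)."""
    df = wide.merge(
        samples.drop(columns=["site_id", "depth", "moisture"]), on="sample_id")
    df["cai"] = df["basal_resp"] / df["sir_resp"]
    df["d_soc"] = df["b_soc"] / df["soc"]
    return df


def gradient_analysis(wide: pd.DataFrame) -> pd.DataFrame:
    """Field-moisture Q10 vs aridity index regressions, per depth x source."""
    rows = []
    field = wide[wide["moisture"] == "field"]
    for depth, grp in field.groupby("depth"):
        for source, col in (("SOC", "q10_soc"), ("SIC", "q10_sic")):
            sub = grp.dropna(subset=[col])
            res = gradient.regress_on_aridity(
                sub[col], sub["aridity_index"], response=f"q10_{source.lower()}")
            rows.append({"depth": depth, "source": source, "slope": res.slope,
                         "slope_per_0p1_ai": res.slope_per_0p1_ai,
                         "intercept": res.intercept, "r": res.r,
                         "p_value": res.p_value, "ci95_low": res.ci95[0],
                         "ci95_high": res.ci95[1], "n": res.n})
    return pd.DataFrame(rows)


def moisture_tests(wide: pd.DataFrame) -> pd.DataFrame:
    """Paired t tests between WHC treatments, per depth x source."""
    levels = [m for m in wide["moisture"].unique() if m in WHC_INDEX]
    levels.sort(key=WHC_INDEX.get)
    rows = []
    for depth, grp in wide.groupby("depth"):
        for source, col in (("SOC", "q10_soc"), ("SIC", "q10_sic")):
            pivot = grp.pivot_table(index="site_id", columns="moisture",
                                    values=col, aggfunc="first")
            for i, a in enumerate(levels):
                for b in levels[i + 1:]:
                    if a not in pivot.columns or b not in pivot.columns:
                        continue
                    res = gradient.paired_treatment_test(pivot[a], pivot[b])
                    rows.append({
                        "depth": depth, "source": source,
                        "treatment_a": a, "treatment_b": b,
                        "t": res.t, "df": res.df, "p_value": res.p_value,
                        "mean_difference": res.mean_difference,
                        "degenerate": res.degenerate,
                    })
    return pd.DataFrame(rows)


def correlation_analysis(factors: pd.DataFrame, holm: bool = True) -> pd.DataFrame:
    """Field-moisture Pearson screen of Q10s against all factors, per depth."""
    out = []
    field = factors[factors["moisture"] == "field"]
    for depth, grp in field.groupby("depth"):
        tab = gradient.correlation_table(
            grp[["q10_soc", "q10_sic"]], grp[FACTOR_COLUMNS], holm=holm)
        tab.insert(0, "depth", depth)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def path_analysis(factors: pd.DataFrame, config: RunConfig, depth: str = "topsoil"):
    """Composite construction and path models for both responses at one depth.

    Returns ``{response: (PathModel, composite specs)}`` fitted on
    field-moisture samples with complete data.
    """
    field = factors[(factors["moisture"] == "field") & (factors["depth"] == depth)]
    results = {}
    for response in ("q10_soc", "q10_sic"):
        cols = sorted({m for ms in config.composites.values() for m in ms})
        data = field.dropna(subset=cols + [response])
        scores, specs = pathmodel.build_composites(data, config.composites)
        scores = scores.copy()
        scores[response] = data[response].to_numpy()
        model = pathmodel.fit_path_model(scores, config.dag, response)
        results[response] = (model, specs)
    return results


def run_all(config: RunConfig, out_dir, in_dir=None) -> dict:
    """Full pipeline: simulate (or load), analyse, write outputs, summarise.

    Writes every stage table plus a machine-readable summary.json; returns
    the summary dict.  Identical config and seed give byte-identical output.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if in_dir is None:
        import dataclasses
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen, config.protocol, config.end_members)
        log.info("simulated cohort: %d sites, %d samples (seed %d)",
                 len(cohort.sites), len(cohort.samples), config.seed)
        cohort.write(out)
    else:
        cohort = read_tables(in_dir)

    part = partition_at(cohort, config)
    part.to_csv(out / "partition.csv", index=False)
    fits = q10mod.fit_cohort(part, qc=config.qc)
    meta = cohort.samples[["sample_id", "site_id", "depth", "moisture"]]
    fits_meta = fits.merge(meta, on="sample_id")
    fits_meta.to_csv(out / "q10.csv", index=False)
    wide = q10_wide(fits_meta, cohort.sites)
    factors = build_factors(wide, cohort.samples)

    grad = gradient_analysis(wide)
    grad.to_csv(out / "gradient.csv", index=False)

    n_whc = sum(m in WHC_INDEX for m in wide["moisture"].unique())
    if n_whc >= 2:
        ttests = moisture_tests(wide)
        ttests.to_csv(out / "ttests.csv", index=False)
    else:
        ttests = pd.DataFrame()
        log.info("fewer than 2 WHC treatments present; paired-test stage skipped")

    corr = correlation_analysis(factors, holm=config.holm_correction)
    corr.to_csv(out / "correlations.csv", index=False)

    paths = path_analysis(factors, config)
    edge_rows, effect_rows, fit_rows = [], [], []
    for response, (model, _specs) in paths.items():
        for (s, d), c in model.edges.items():
            edge_rows.append({"response": response, "from": s, "to": d,
                              "coefficient": c})
        eff = model.effects.copy()
        eff.insert(0, "response", response)
        effect_rows.append(eff)
        fit_rows.append({"response": response, "n": model.n, **model.fit})
    pd.DataFrame(edge_rows).to_csv(out / "pathmodel.csv", index=False)
    pd.concat(effect_rows).to_csv(out / "effects.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "fit.csv", index=False)

    upscale = upscaling.run_upscaling(config.upscaling, config.rounding)
    with open(out / "upscaling.json", "w", encoding="utf-8") as fh:
        json.dump(upscale.__dict__, fh, indent=2)

    summary = {
        "seed": config.seed,
        "n_sites": int(len(cohort.sites)),
        "n_samples": int(len(cohort.samples)),
        "qc_pass_fraction": float(fits["qc_pass"].mean()),
        "gradient": grad.to_dict(orient="records"),
        "upscaling": upscale.__dict__,
    }
    if not ttests.empty:
        summary["n_paired_tests"] = int(len(ttests))
    if not cohort.truth.empty:
        merged = wide.merge(cohort.truth, on="sample_id")
        err = np.nanmax(np.abs(np.concatenate([
            (merged["q10_soc"] - merged["true_q10_soc"]).to_numpy(float)
            / merged["true_q10_soc"].to_numpy(float),
            (merged["q10_sic"] - merged["true_q10_sic"]).to_numpy(float)
            / merged["true_q10_sic"].to_numpy(float),
        ])))
        summary["max_abs_rel_q10_error_vs_truth"] = float(err)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
    log.info("pipeline complete; outputs in %s", out)
    return summary
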