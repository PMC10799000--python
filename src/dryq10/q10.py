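"""Exponential temperature-response fits and substrate indices.

Rates are modelled as R = B * exp(k * T) over the 5-30 degC ramp; Q10 is
exp(10 k).  The fit is ordinary least squares on ln(R) against T, which is
closed-form, deterministic and exact in the noiseless limit; nonlinear least
squares on the raw scale is available as a sensitivity option.  Fits are
gated by the R2 of the log-linear regression: > 0.95 for SOC-derived (and
total) CO2, > 0.85 for SIC-derived CO2, with at least four strictly positive
rate points out of the six temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import QCThresholds


@dataclass(frozen=True)
class Q10Fit:
    sample_id: str
    source: str  # "SOC" | "SIC" | "total"
    B: float  # rate at 0 degC, ug C g-1 h-1
    k: float  # per degC
    q10: float  # exp(10 k)
    r_squared: float
    n_points: int
    qc_pass: bool
    reason: str = ""


def q10_from_k(k: float) -> float:
    """Q10 = exp(10 k): the rate multiplier per 10 degC of warming."""
    return float(np.exp(10.0 * np.asarray(k)))


def _refused(sample_id: str, source: str, n: int, reason: str) -> Q10Fit:
    return Q10Fit(sample_id, source, float("nan"), float("nan"), float("nan"),
                  float("nan"), n, False, reason)


def fit_exponential(
    temperatures,
    rates,
    sample_id: str = "",
    source: str = "total",
    qc: QCThresholds = QCThresholds(),
    method: str = "ols",
) -> Q10Fit:
    """Fit R = B exp(kT) to one sample x source temperature series.

    Non-positive (or NaN) rate points are dropped before fitting; the fit is
    refused, with a reason, when fewer than ``qc.min_points`` positive points
    remain.  ``method`` is "ols" (log-linear least squares, default) or "nls"
    (Levenberg-Marquardt on the raw scale, initialised from the OLS fit).
    R2 is always that of the log-linear regression, so the QC gate does not
    depend on the estimation method.
    """
    t = np.asarray(temperatures, float)
    r = np.asarray(rates, float)
    keep = np.isfinite(r) & (r > 0) & np.isfinite(t)
    t, r = t[keep], r[keep]
    n = int(keep.sum())
    if n < qc.min_points:
        return _refused(sample_id, source,
                        n, f"only {n} positive points (< {qc.min_points})")
    if np.unique(t).size < 2:
        return _refused(sample_id, source, n, "fewer than 2 distinct temperatures")

    y = np.log(r)
    k, lnb = np.polyfit(t, y, 1)
    resid = y - (lnb + k * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # flat series: k = 0 exactly, R2 undefined -> QC fail
        return Q10Fit(sample_id, source, float(np.exp(lnb)), 0.0, 1.0,
                      float("nan"), n, False, "flat series, R2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    b = float(np.exp(lnb))
    k = float(k)

    if method == "nls":
        try:
            (b, k), _ = curve_fit(
                lambda tt, bb, kk: bb * np.exp(kk * tt), t, r, p0=(b, k), maxfev=10000)
        except RuntimeError:
            return _refused(sample_id, source, n, "nonlinear fit did not converge")
    elif method != "ols":
        raise ValueError(f"unknown fit method {method!r}")

    threshold = qc.r2_sic if source == "SIC" else qc.r2_soc
    qc_pass = bool(r2 > threshold)
    return Q10Fit(sample_id, source, b, k, q10_from_k(k), float(r2), n, qc_pass,
                  "" if qc_pass else f"R2 {r2:.3f} <= {threshold}")


def qc_fit(fit: Q10Fit, qc: QCThresholds = QCThresholds()) -> bool:
    """QC gate: R2 above the per-source threshold (total uses the SOC one)."""
    if not np.isfinite(fit.r_squared):
        return False
    threshold = qc.r2_sic if fit.source == "SIC" else qc.r2_soc
    return bool(fit.r_squared > threshold)


def fit_cohort(
    partition: pd.DataFrame,
    qc: QCThresholds = QCThresholds(),
    method: str = "ols",
    sources: tuple = ("SOC", "SIC", "total"),
) -> pd.DataFrame:
    """Per-sample exponential fits for each CO2 source.

    ``partition`` holds one row per sample x temperature with r_soc, r_sic
    and rate_total columns (the partition table).  Returns one row per
    sample x source with B, k, q10, r_squared, n_points, qc_pass.
    """
    col = {"SOC": "r_soc", "SIC": "r_sic", "total": "rate_total"}
    rows = []
    for sample_id, grp in partition.groupby("sample_id", sort=True):
        for source in sources:
            fit = fit_exponential(
                grp["temperature_C"], grp[col[source]],
                sample_id=sample_id, source=source, qc=qc, method=method)
            rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def carbon_availability_index(basal_resp: float, sir_resp: float) -> float:
    """CAI: basal respiration over substrate-induced respiration."""
    if sir_resp <= 0:
        raise ValueError("substrate-induced respiration must be positive")
    return basal_resp / sir_resp


def soc_decomposability(b_soc: float, soc_content: float) -> float:
    """D_SOC: fitted basal rate parameter B per unit SOC content."""
    if soc_content <= 0:
        raise ValueError("SOC content must be positive")
    return b_soc / soc_content


def sic_from_carbonate(caco3_g_kg: float) -> float:
    """SIC (g C kg-1) from CaCO3 content via the 0.12 carbon mass fraction."""
    if np.any(np.asarray(caco3_g_kg) < 0):
        raise ValueError("carbonate content must be non-negative")
    return 0.12 * caco3_g_kg
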