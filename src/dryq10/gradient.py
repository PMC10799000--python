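"""Aridity-gradient statistics: regressions, paired moisture tests, correlations.

Field-moisture Q10s are regressed on the aridity index (slope also reported
per 0.1 AI, the scale on which dryland aridity scenarios are usually
phrased); WHC treatments are compared with classical paired t tests by site;
and Q10 is screened against climate, physical, chemical and substrate
factors with Pearson correlations, optionally Holm-corrected per response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RegressionResult:
    response: str
    slope: float  # per unit AI
    slope_per_0p1_ai: float
    intercept: float
    r: float
    p_value: float
    ci95: tuple  # on the slope
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


def regress_on_aridity(values, ai, response: str = "") -> RegressionResult:
    """OLS of a per-site quantity on the aridity index, with slope CI."""
    y = np.asarray(values, float)
    x = np.asarray(ai, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 sites for the aridity regression")
    if np.ptp(x) == 0:
        raise ValueError("aridity index has zero variance")
    if np.ptp(y) == 0:
        # flat response: slope and correlation are exactly zero
        return RegressionResult(response, 0.0, 0.0, float(y[0]), 0.0, 1.0,
                                (0.0, 0.0), n)
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        response=response,
        slope=float(res.slope),
        slope_per_0p1_ai=float(res.slope) / 10.0,
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        ci95=(float(ci[0]), float(ci[1])),
        n=n,
    )


def paired_treatment_test(a, b) -> PairedTestResult:
    """Two-sided paired t test between two site-matched treatments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # all differences identical: t undefined unless the mean is 0 too
        t = 0.0 if np.allclose(d, 0.0) else np.inf * np.sign(d.mean())
        p = 1.0 if t == 0.0 else 0.0
        return PairedTestResult(float(t), n - 1, p, float(d.mean()), degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        float(res.statistic), n - 1, float(res.pvalue), float(d.mean()))


def significance_code(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    q10s: pd.DataFrame,
    factors: pd.DataFrame,
    holm: bool = True,
) -> pd.DataFrame:
    """Pearson correlations of each Q10 response against each factor.

    ``q10s`` and ``factors`` are sample-aligned DataFrames (rows matched by
    index).  Significance is optionally Holm-corrected within each response
    row before coding.  Constant factor columns yield NaN r with a flag
    rather than an exception.
    """
    q10s, factors = q10s.align(factors, join="inner", axis=0)
    rows = []
    for response in q10s.columns:
        y = q10s[response].to_numpy(float)
        rs, ps, flags = [], [], []
        for factor in factors.columns:
            x = factors[factor].to_numpy(float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                rs.append(np.nan); ps.append(np.nan); flags.append("constant")
                continue
            r, p = stats.pearsonr(x[keep], y[keep])
            rs.append(float(r)); ps.append(float(p)); flags.append("")
        ps = np.asarray(ps)
        p_adj = np.full_like(ps, np.nan)
        ok = np.isfinite(ps)
        if holm and ok.any():
            p_adj[ok] = multipletests(ps[ok], method="holm")[1]
        elif ok.any():
            p_adj[ok] = ps[ok]
        for factor, r, p, pa, flag in zip(factors.columns, rs, ps, p_adj, flags):
            rows.append({
                "response": response, "factor": factor, "r": r,
                "p": p, "p_adjusted": pa,
                "significance": significance_code(pa), "flag": flag,
            })
    return pd.DataFrame(rows)
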