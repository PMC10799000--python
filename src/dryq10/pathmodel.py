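"""PCA composites and recursive path analysis with effect decomposition.

Each factor group (climate, physical, chemical, substrate) is collapsed to
the first principal component of its standardized members; the composites
and the response then enter a recursive (acyclic) system of linear
structural equations.  Each equation is estimated by least squares on
standardized variables, which coincides with maximum likelihood for a
recursive, fully observed system, so the standardized coefficients are the
ML path coefficients.  Effects decompose as

    total(j -> response) = direct (the j -> response edge, 0 if absent)
                         + indirect (sum over all other directed paths of the
                           products of edge coefficients)

and model fit is judged by the ML discrepancy chi-square, RMSEA and GFI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CompositeSpec:
    name: str
    members: tuple
    loadings: tuple = ()
    variance_explained: float = float("nan")


@dataclass
class PathModel:
    variables: list  # topological-compatible ordering, response last
    response: str
    edges: dict  # (src, dst) -> standardized coefficient
    b_matrix: np.ndarray  # B[i, j]: coefficient of variable j in equation for i
    residual_variances: dict  # endogenous variable -> residual variance
    exogenous: list
    effects: pd.DataFrame = field(default=None)
    fit: dict = field(default_factory=dict)
    n: int = 0


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def composite_scores(data: pd.DataFrame, spec: CompositeSpec):
    """First principal component of a variable group's correlation matrix.

    Members are standardized to mean 0, SD 1; loadings are the unit-norm
    leading eigenvector, with the sign fixed so the first listed member
    loads positively (removing eigenvector sign ambiguity).  Returns
    ``(scores, fitted_spec)``.
    """
    if len(spec.members) < 2:
        raise ValueError(f"composite {spec.name!r} needs at least 2 members")
    for m in spec.members:
        if m not in data.columns:
            raise KeyError(f"composite {spec.name!r}: column {m!r} missing")
        if np.ptp(data[m].to_numpy(float)) == 0:
            raise ValueError(f"composite {spec.name!r}: column {m!r} is constant")
    x = data[list(spec.members)].to_numpy(float)
    z = _standardize(x)
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    # orient by the first listed member (first non-zero loading as fallback)
    anchor = v[0] if v[0] != 0 else v[np.nonzero(v)[0][0]]
    if anchor < 0:
        v = -v
    scores = z @ v
    fitted = CompositeSpec(
        name=spec.name,
        members=spec.members,
        loadings=tuple(float(l) for l in v),
        variance_explained=float(eigvals[-1] / eigvals.sum()),
    )
    return pd.Series(scores, index=data.index, name=spec.name), fitted


def build_composites(data: pd.DataFrame, groups: dict):
    """Composite scores for every group; returns (scores frame, fitted specs)."""
    scores, specs = {}, {}
    for name, members in groups.items():
        s, spec = composite_scores(data, CompositeSpec(name, tuple(members)))
        scores[name] = s
        specs[name] = spec
    return pd.DataFrame(scores), specs


def _topological_order(nodes, edges):
    children = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for s, d in edges:
        children[s].append(d)
        indeg[d] += 1
    order, stack = [], sorted(v for v in nodes if indeg[v] == 0)
    while stack:
        v = stack.pop(0)
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
        stack.sort()
    if len(order) != len(nodes):
        raise ValueError("path-model DAG contains a cycle")
    return order


def fit_path_model(data: pd.DataFrame, dag, response: str) -> PathModel:
    """Estimate a recursive path model on standardized observed variables.

    ``dag`` is an iterable of (from, to) edges over ``data`` columns; "response"
    may be used as an alias for the response column.  Each endogenous
    variable is regressed on its parents; exogenous covariances are free.
    """
    edges = [(s, response if d == "response" else d) for s, d in dag]
    edges = [(response if s == "response" else s, d) for s, d in edges]
    nodes = sorted({v for e in edges for v in e})
    for v in nodes:
        if v not in data.columns:
            raise KeyError(f"path-model variable {v!r} missing from data")
    order = _topological_order(nodes, edges)
    n, p = len(data), len(nodes)
    n_params = len(edges)
    if n <= n_params + 1:
        raise ValueError("too few observations for the number of path parameters")

    z = pd.DataFrame(
        _standardize(data[order].to_numpy(float)), columns=order, index=data.index)
    idx = {v: i for i, v in enumerate(order)}
    parents = {v: [s for s, d in edges if d == v] for v in order}
    exogenous = [v for v in order if not parents[v]]

    b = np.zeros((p, p))
    resid_var = {}
    for v in order:
        pa = parents[v]
        if not pa:
            continue
        x = z[pa].to_numpy()
        y = z[v].to_numpy()
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        for name, c in zip(pa, coef):
            b[idx[v], idx[name]] = c
        resid = y - x @ coef
        resid_var[v] = float(resid @ resid / (n - 1))

    model = PathModel(
        variables=order,
        response=response,
        edges={(s, d): float(b[idx[d], idx[s]]) for s, d in edges},
        b_matrix=b,
        residual_variances=resid_var,
        exogenous=exogenous,
        n=n,
    )
    model.effects = effect_decomposition(model)
    s_cov = np.cov(z.to_numpy(), rowvar=False)
    model.fit = fit_statistics(model, s_cov, n)
    return model


def total_effect_matrix(b: np.ndarray) -> np.ndarray:
    """Sum of coefficient products over all directed paths: (I-B)^-1 - I."""
    p = b.shape[0]
    return np.linalg.inv(np.eye(p) - b) - np.eye(p)


def effect_decomposition(model: PathModel) -> pd.DataFrame:
    """Standardized direct, indirect and total effects on the response."""
    t = total_effect_matrix(model.b_matrix)
    idx = {v: i for i, v in enumerate(model.variables)}
    ri = idx[model.response]
    rows = []
    for v in model.variables:
        if v == model.response:
            continue
        direct = model.edges.get((v, model.response), 0.0)
        total = float(t[ri, idx[v]])
        rows.append({
            "predictor": v,
            "direct": direct,
            "indirect": total - direct,
            "total": total,
        })
    return pd.DataFrame(rows)


def implied_covariance(model: PathModel, sample_cov: np.ndarray) -> np.ndarray:
    """Model-implied covariance (I-B)^-1 Psi (I-B)^-T on the model's ordering.

    Psi carries the free exogenous (co)variances, taken at their sample
    values, and the endogenous residual variances on the diagonal.
    """
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    psi = np.zeros((p, p))
    exo_idx = [idx[v] for v in model.exogenous]
    for i in exo_idx:
        for j in exo_idx:
            psi[i, j] = sample_cov[i, j]
    for v, rv in model.residual_variances.items():
        psi[idx[v], idx[v]] = rv
    inv = np.linalg.inv(np.eye(p) - model.b_matrix)
    return inv @ psi @ inv.T


def fit_statistics(model: PathModel, sample_cov: np.ndarray, n: int) -> dict:
    """ML discrepancy chi-square, df, p, RMSEA and GFI for the fitted model.

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p; chi2 = (n-1) F;
    df = p(p+1)/2 minus free parameters (edges, residual variances, exogenous
    (co)variances); RMSEA = sqrt(max(0, chi2-df) / (df (n-1))) (0 at df = 0).
    """
    s = np.asarray(sample_cov, float)
    p = len(model.variables)
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise ValueError("sample covariance is not positive definite")
    sigma = implied_covariance(model, s)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_m <= 0:
        raise ValueError("implied covariance is not positive definite")
    sigma_inv = np.linalg.inv(sigma)
    f_ml = float(logdet_m + np.trace(s @ sigma_inv) - logdet_s - p)
    f_ml = max(f_ml, 0.0)
    n_exo = len(model.exogenous)
    free = len(model.edges) + len(model.residual_variances) + n_exo * (n_exo + 1) // 2
    df = p * (p + 1) // 2 - free
    chi2 = (n - 1) * f_ml
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = float(np.sqrt(max(0.0, chi2 - df) / (df * (n - 1)))) if df > 0 else 0.0
    a = sigma_inv @ s - np.eye(p)
    denom = float(np.trace((sigma_inv @ s) @ (sigma_inv @ s)))
    gfi = 1.0 - float(np.trace(a @ a)) / denom if denom > 0 else float("nan")
    return {"chi2": chi2, "df": df, "p": p_value, "rmsea": rmsea, "gfi": gfi}
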