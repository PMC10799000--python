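"""Composites, structural equations, effect decomposition, fit indices."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dryq10 import fit_path_model
from dryq10.pathmodel import (
    CompositeSpec,
    PathModel,
    composite_scores,
    effect_decomposition,
    fit_statistics,
    implied_covariance,
    total_effect_matrix,
)


def brute_force_total_effects(variables, edges, response):
    """Oracle: enumerate every directed path and sum coefficient products."""
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    for (s, d), c in edges.items():
        g.add_edge(s, d, coef=c)
    totals = {}
    for v in variables:
        if v == response:
            continue
        total = 0.0
        for path in nx.all_simple_paths(g, v, response):
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= g[a][b]["coef"]
            total += prod
        totals[v] = total
    return totals


def make_model(variables, edges, response):
    idx = {v: i for i, v in enumerate(variables)}
    b = np.zeros((len(variables),) * 2)
    for (s, d), c in edges.items():
        b[idx[d], idx[s]] = c
    endo = {d for _, d in edges}
    return PathModel(variables=list(variables), response=response, edges=dict(edges),
                     b_matrix=b, residual_variances={v: 1.0 for v in endo},
                     exogenous=[v for v in variables if v not in endo], n=100)


class TestCompositeScores:
    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 20)
        data = pd.DataFrame({"a": x, "b": 3 * x + 1})
        _, spec = composite_scores(data, CompositeSpec("g", ("a", "b")))
        assert spec.variance_explained == pytest.approx(1.0)

    def test_orthogonal_pair_splits_variance(self):
        data = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0],
                             "b": [1.0, 1.0, -1.0, -1.0]})
        _, spec = composite_scores(data, CompositeSpec("g", ("a", "b")))
        assert spec.variance_explained == pytest.approx(0.5)

    def test_loadings_unit_norm_and_anchor_positive(self, factors):
        field = factors[(factors.moisture == "field") & (factors.depth == "topsoil")]
        _, spec = composite_scores(
            field, CompositeSpec("chemical", ("ph", "cec", "ca", "mg")))
        assert np.linalg.norm(spec.loadings) == pytest.approx(1.0)
        assert spec.loadings[0] > 0

    def test_negating_member_flips_its_loading_only(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=40)
        data = pd.DataFrame({"a": base + rng.normal(0, 0.4, 40),
                             "b": base + rng.normal(0, 0.4, 40)})
        s0, spec0 = composite_scores(data, CompositeSpec("g", ("a", "b")))
        flipped = data.assign(b=-data["b"])
        s1, spec1 = composite_scores(flipped, CompositeSpec("g", ("a", "b")))
        assert spec1.loadings[1] == pytest.approx(-spec0.loadings[1])
        assert abs(np.corrcoef(s0, s1)[0, 1]) == pytest.approx(1.0)

    def test_constant_column_error_names_column(self):
        data = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        with pytest.raises(ValueError, match="'b'"):
            composite_scores(data, CompositeSpec("g", ("a", "b")))


class TestFitPathModel:
    def test_single_edge_equals_pearson_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        data = pd.DataFrame({"x": x, "y": y})
        model = fit_path_model(data, [("x", "y")], "y")
        r = stats.pearsonr(x, y).statistic
        assert model.edges[("x", "y")] == pytest.approx(r, rel=1e-9)

    def test_chain_recovery(self):
        rng = np.random.default_rng(2)
        n = 10_000
        x = rng.normal(size=n)
        m = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        y = 0.5 * m + np.sqrt(1 - 0.25) * rng.normal(size=n)
        model = fit_path_model(pd.DataFrame({"x": x, "m": m, "y": y}),
                               [("x", "m"), ("m", "y")], "y")
        assert model.edges[("x", "m")] == pytest.approx(0.6, abs=0.03)
        assert model.edges[("m", "y")] == pytest.approx(0.5, abs=0.03)

    def test_saturated_model_reproduces_sample_covariance(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        dag = [("a", "b"), ("a", "c"), ("b", "c")]
        model = fit_path_model(data, dag, "c")
        z = (data - data.mean()) / data.std(ddof=1)
        s = np.cov(z[model.variables].to_numpy(), rowvar=False)
        np.testing.assert_allclose(implied_covariance(model, s), s, atol=1e-10)
        assert model.fit["chi2"] == pytest.approx(0.0, abs=1e-8)
        assert model.fit["df"] == 0
        assert model.fit["rmsea"] == 0.0
        assert model.fit["gfi"] == pytest.approx(1.0, abs=1e-8)

    def test_cyclic_dag_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 2)),
                            columns=["a", "b"])
        with pytest.raises(ValueError, match="cycle"):
            fit_path_model(data, [("a", "b"), ("b", "a")], "b")

    def test_standardized_coefficients_scale_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=150)
        y = 0.4 * x + rng.normal(0, 1, 150)
        d0 = pd.DataFrame({"x": x, "y": y})
        d1 = pd.DataFrame({"x": 100 * x + 7, "y": 0.01 * y - 3})
        m0 = fit_path_model(d0, [("x", "y")], "y")
        m1 = fit_path_model(d1, [("x", "y")], "y")
        assert m1.edges[("x", "y")] == pytest.approx(m0.edges[("x", "y")], rel=1e-9)


class TestEffectDecomposition:
    def test_chain_with_direct_edge_by_hand(self):
        # x -> m (0.6), m -> y (0.5), x -> y (-0.2): indirect 0.30, total 0.10
        model = make_model(["x", "m", "y"],
                           {("x", "m"): 0.6, ("m", "y"): 0.5, ("x", "y"): -0.2}, "y")
        eff = effect_decomposition(model).set_index("predictor")
        assert eff.loc["x", "direct"] == pytest.approx(-0.2)
        assert eff.loc["x", "indirect"] == pytest.approx(0.30)
        assert eff.loc["x", "total"] == pytest.approx(0.10)

    def test_no_outgoing_paths_zero_effects(self):
        model = make_model(["x", "y", "z"], {("x", "y"): 0.5}, "y")
        eff = effect_decomposition(model).set_index("predictor")
        assert eff.loc["z"].abs().sum() == 0.0

    def test_total_equals_direct_plus_indirect_exactly(self, factors, run_config):
        from dryq10.pipeline import path_analysis
        for model, _ in path_analysis(factors, run_config).values():
            eff = model.effects
            np.testing.assert_array_equal(
                eff["total"].to_numpy(), (eff["direct"] + eff["indirect"]).to_numpy())

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration_on_random_dags(self, seed):
        """Matrix-series totals equal exhaustive path enumeration (<= 6 nodes)."""
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(3, 7))
        variables = [f"v{i}" for i in range(n_nodes)]
        edges = {}
        for i, j in itertools.combinations(range(n_nodes), 2):
            if rng.random() < 0.6:  # i < j keeps the graph acyclic
                edges[(variables[i], variables[j])] = float(rng.normal())
        response = variables[-1]
        model = make_model(variables, edges, response)
        eff = effect_decomposition(model).set_index("predictor")
        oracle = brute_force_total_effects(variables, edges, response)
        for v, total in oracle.items():
            assert eff.loc[v, "total"] == pytest.approx(total, abs=1e-10)


class TestFitStatistics:
    def test_identity_discrepancy_is_zero(self):
        model = make_model(["x", "y"], {("x", "y"): 0.0}, "y")
        s = np.eye(2)
        fitstats = fit_statistics(model, s, 50)
        assert fitstats["chi2"] == pytest.approx(0.0, abs=1e-10)

    def test_chi2_distribution_under_true_model(self):
        """Data simulated from the fitted DAG: chi2 mean tracks its df."""
        rng = np.random.default_rng(10)
        n, reps = 400, 400
        chi2s, df = [], None
        dag = [("x", "m"), ("m", "y")]  # omits x->y and exogenous links: df > 0
        for _ in range(reps):
            x = rng.normal(size=n)
            m = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
            y = 0.5 * m + np.sqrt(1 - 0.25) * rng.normal(size=n)
            model = fit_path_model(pd.DataFrame({"x": x, "m": m, "y": y}), dag, "y")
            chi2s.append(model.fit["chi2"])
            df = model.fit["df"]
        assert df > 0
        assert np.mean(chi2s) == pytest.approx(df, rel=0.10)

    def test_singular_covariance_rejected(self):
        model = make_model(["x", "y"], {("x", "y"): 0.5}, "y")
        s = np.ones((2, 2))
        with pytest.raises(ValueError, match="positive definite"):
            fit_statistics(model, s, 50)
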