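"""Correlations, RT similarity, edge integration, selection and topology."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtnets.config import MixConfig
from rtnets.errors import EmptyNetworkError, InsufficientDataError
from rtnets.network import (
    CorrelationSet,
    expression_correlations,
    integrate_edges,
    partial_correlations,
    rt_profile_correlation,
    rt_similarity,
    select_edges,
    topology_metrics,
)


def _mix(**kw) -> MixConfig:
    base = dict(alpha=1.0, beta_mix=0.0, gamma=0.0, min_abs_corr=0.0, tau=-10.0)
    base.update(kw)
    return MixConfig(**base)


# ------------------------------------------------------------ correlations


def test_affine_relation_gives_unit_correlation():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    expr = pd.DataFrame({"s%d" % i: [x[i], 2 * x[i] + 1] for i in range(50)},
                        index=["Ga", "Gb"])
    cset = expression_correlations(expr, min_samples=5)
    assert cset.r.loc["Ga", "Gb"] == pytest.approx(1.0, abs=1e-12)


def test_correlations_match_closed_form():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(3, 30))
    expr = pd.DataFrame(x, index=["G1", "G2", "G3"],
                        columns=[f"s{i}" for i in range(30)])
    cset = expression_correlations(expr, min_samples=5)
    expected = np.corrcoef(x)
    np.testing.assert_allclose(cset.r.to_numpy(), expected, atol=1e-12)


def test_independent_genes_have_small_correlation():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(rng.normal(size=(2, 1000)), index=["G1", "G2"])
    cset = expression_correlations(expr, min_samples=5)
    assert abs(cset.r.loc["G1", "G2"]) < 0.1


def test_zero_variance_and_sparse_genes_dropped():
    expr = pd.DataFrame(
        {
            f"s{i}": [1.0, float(i), float(i) ** 2, np.nan if i > 2 else float(i)]
            for i in range(10)
        },
        index=["const", "G1", "G2", "sparse"],
    )
    with pytest.warns(UserWarning):
        cset = expression_correlations(expr, min_samples=5)
    assert set(cset.genes) == {"G1", "G2"}
    with pytest.raises(InsufficientDataError):
        expression_correlations(expr.loc[["const", "sparse"]], min_samples=5)


# ------------------------------------------------------ partial correlations


def _residual_partial_corr(x: np.ndarray, i: int, j: int) -> float:
    """Oracle: correlation of residuals after regressing out all others."""
    others = [k for k in range(x.shape[0]) if k not in (i, j)]
    z = np.vstack([np.ones(x.shape[1]), x[others]]).T
    ri = x[i] - z @ np.linalg.lstsq(z, x[i], rcond=None)[0]
    rj = x[j] - z @ np.linalg.lstsq(z, x[j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


def test_diagonal_covariance_gives_zero_partials():
    genes = ["G1", "G2", "G3"]
    eye = pd.DataFrame(np.diag([1.0, 2.0, 3.0]), index=genes, columns=genes)
    cset = CorrelationSet(genes=genes, r=eye, sigma=eye)
    out = partial_correlations(cset, ridge=0.0)
    off = out.rho.to_numpy()[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 0.0, atol=1e-12)


def test_chain_partial_correlation_vanishes():
    rng = np.random.default_rng(3)
    n = 4000
    x = rng.normal(size=n)
    y = x + 0.5 * rng.normal(size=n)
    z = y + 0.5 * rng.normal(size=n)
    expr = pd.DataFrame([x, y, z], index=["X", "Y", "Z"])
    cset = partial_correlations(expression_correlations(expr, 5), ridge=0.0)
    assert cset.r.loc["X", "Z"] > 0.5
    assert abs(cset.rho.loc["X", "Z"]) < 0.05
    oracle = _residual_partial_corr(np.vstack([x, y, z]), 0, 2)
    assert cset.rho.loc["X", "Z"] == pytest.approx(oracle, abs=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_precision_partials_match_residual_regression(seed):
    rng = np.random.default_rng(seed)
    p, n = rng.integers(3, 7), 400
    x = rng.normal(size=(p, n))
    a = rng.normal(size=(p, p))
    x = a @ x  # correlated genes
    expr = pd.DataFrame(x, index=[f"G{i}" for i in range(p)])
    cset = partial_correlations(expression_correlations(expr, 5), ridge=0.0)
    for i in range(p):
        for j in range(i + 1, p):
            oracle = _residual_partial_corr(x, i, j)
            assert cset.rho.iloc[i, j] == pytest.approx(oracle, abs=1e-8)


# ------------------------------------------------------------ RT similarity


def test_rt_similarity_direct_formula():
    s = rt_similarity(pd.Series({"G1": 0.0, "G2": 1.0, "G3": 0.5}))
    assert s.loc["G1", "G2"] == pytest.approx(0.0)
    assert s.loc["G1", "G3"] == pytest.approx(0.5)
    assert s.loc["G1", "G1"] == 1.0


def test_rt_similarity_degenerate_and_missing():
    s = rt_similarity(pd.Series({"G1": 0.3, "G2": 0.3, "G3": 0.3}))
    assert (s.to_numpy() == 1.0).all()
    s2 = rt_similarity(pd.Series({"G1": 0.0, "G2": 1.0, "G3": np.nan}))
    assert s2.loc["G1", "G3"] == 0.5 and s2.loc["G3", "G2"] == 0.5


def test_rt_similarity_matches_brute_force():
    rng = np.random.default_rng(5)
    vals = pd.Series(rng.normal(size=10), index=[f"G{i}" for i in range(10)])
    s = rt_similarity(vals)
    spread = vals.max() - vals.min()
    for a in vals.index:
        for b in vals.index:
            expected = 1 - abs(vals[a] - vals[b]) / spread if a != b else 1.0
            assert s.loc[a, b] == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------- RT profile correlation


def test_profile_correlation_is_rank_invariant():
    base = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
    profiles = pd.DataFrame(
        {"s%d" % i: [base[i], np.exp(base[i]), -base[i]] for i in range(5)},
        index=["G1", "G2", "G3"],
    )
    corr = rt_profile_correlation(profiles)
    assert corr.loc["G1", "G2"] == pytest.approx(1.0)
    assert corr.loc["G1", "G3"] == pytest.approx(-1.0)


def test_profile_correlation_matches_spearman_oracle():
    rng = np.random.default_rng(6)
    profiles = pd.DataFrame(rng.normal(size=(4, 20)),
                            index=["G1", "G2", "G3", "G4"])
    corr = rt_profile_correlation(profiles)
    for i in range(4):
        for j in range(4):
            rho = stats.spearmanr(profiles.iloc[i], profiles.iloc[j]).statistic
            assert corr.iloc[i, j] == pytest.approx(rho, abs=1e-12)


def test_constant_profile_reports_zero_with_warning():
    profiles = pd.DataFrame(
        [[1.0, 1.0, 1.0, 1.0], [0.1, 0.4, 0.2, 0.8]], index=["Gc", "G1"]
    )
    with pytest.warns(UserWarning):
        corr = rt_profile_correlation(profiles)
    assert corr.loc["Gc", "G1"] == 0.0


# ------------------------------------------------------------- integration


def _toy_cset(r: np.ndarray, genes) -> CorrelationSet:
    df = pd.DataFrame(r, index=genes, columns=genes)
    return CorrelationSet(genes=list(genes), r=df, sigma=df)


def test_rna_only_mix_reproduces_w_rna():
    rng = np.random.default_rng(7)
    r = np.corrcoef(rng.normal(size=(4, 40)))
    cset = _toy_cset(r, ["G1", "G2", "G3", "G4"])
    edges = integrate_edges(cset, None, _mix())
    np.testing.assert_allclose(edges["w_int"], edges["w_rna"], atol=0)


def test_pure_rt_mix_with_unit_similarity():
    r = np.array([[1, 0.9, 0.8], [0.9, 1, 0.7], [0.8, 0.7, 1.0]])
    genes = ["G1", "G2", "G3"]
    cset = _toy_cset(r, genes)
    ones = pd.DataFrame(np.ones((3, 3)), index=genes, columns=genes)
    edges = integrate_edges(cset, ones, _mix(alpha=0.0, beta_mix=1.0))
    np.testing.assert_allclose(edges["w_int"], 1.0)


def test_default_mix_matches_hand_computation():
    rng = np.random.default_rng(8)
    genes = [f"G{i}" for i in range(5)]
    r = np.corrcoef(rng.normal(size=(5, 60)))
    rt = pd.Series(rng.normal(size=5), index=genes)
    cset = _toy_cset(r, genes)
    s = rt_similarity(rt)
    mix = _mix(alpha=1.0, beta_mix=0.5, gamma=0.5)
    edges = integrate_edges(cset, s, mix)
    # explicit spreadsheet-style recomputation
    pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    w = np.array([r[i, j] for i, j in pairs])
    mu, sd = w.mean(), w.std(ddof=0)
    for row in edges.itertuples():
        i, j = genes.index(row.gene_i), genes.index(row.gene_j)
        s_ij = s.loc[row.gene_i, row.gene_j]
        expected = (
            1.0 * r[i, j] + 0.5 * (2 * s_ij - 1) + 0.5 * (r[i, j] - mu) / sd
        )
        assert row.w_int == pytest.approx(expected, abs=1e-12)


def test_min_abs_corr_filters_before_mixing():
    r = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, -0.7], [0.2, -0.7, 1.0]])
    cset = _toy_cset(r, ["G1", "G2", "G3"])
    edges = integrate_edges(cset, None, _mix(min_abs_corr=0.5))
    kept = set(zip(edges["gene_i"], edges["gene_j"]))
    assert kept == {("G1", "G2"), ("G2", "G3")}
    with pytest.raises(EmptyNetworkError):
        integrate_edges(cset, None, _mix(min_abs_corr=0.95))


def test_b_monotonicity_in_signed_similarity():
    rng = np.random.default_rng(9)
    genes = [f"G{i}" for i in range(4)]
    r = np.corrcoef(rng.normal(size=(4, 30)))
    s = rt_similarity(pd.Series(rng.normal(size=4), index=genes))
    low = integrate_edges(_toy_cset(r, genes), s, _mix(beta_mix=0.2))
    high = integrate_edges(_toy_cset(r, genes), s, _mix(beta_mix=0.8))
    for a, b in zip(low.itertuples(), high.itertuples()):
        if a.s_rt_signed > 0:
            assert b.w_int > a.w_int
        elif a.s_rt_signed < 0:
            assert b.w_int < a.w_int


# --------------------------------------------------------------- selection


def _edge_frame(weights):
    return pd.DataFrame(
        {
            "gene_i": [f"A{i}" for i in range(len(weights))],
            "gene_j": [f"B{i}" for i in range(len(weights))],
            "w_rna": weights,
            "s_rt": 0.5,
            "s_rt_signed": 0.0,
            "w_rna_norm": 0.0,
            "w_int": weights,
        }
    )


def test_threshold_and_topk_selection():
    mix = _mix(tau=0.5)
    net = select_edges(_edge_frame([0.6, 0.4]), mix)
    assert len(net.edges) == 1
    mix_k = dataclasses.replace(_mix(tau=0.0), top_k_global=2, top_k_plot=2)
    net2 = select_edges(_edge_frame([0.9, 0.8, 0.7]), mix_k)
    assert sorted(net2.edges["w_int"]) == [0.8, 0.9]
    with pytest.raises(EmptyNetworkError):
        select_edges(_edge_frame([0.1]), _mix(tau=0.5))


def test_selection_matches_sort_and_slice_oracle():
    rng = np.random.default_rng(10)
    weights = rng.normal(size=100)
    mix = dataclasses.replace(_mix(tau=-0.5), top_k_global=30, top_k_plot=10)
    net = select_edges(_edge_frame(weights), mix)
    expected = sorted(w for w in weights if w >= -0.5)[::-1][:30]
    assert sorted(net.edges["w_int"]) == sorted(expected)
    assert len(net.plot_edges) == 10


def test_threshold_then_topk_is_idempotent():
    rng = np.random.default_rng(12)
    weights = rng.normal(size=50)
    mix = dataclasses.replace(_mix(tau=0.0), top_k_global=20, top_k_plot=5)
    net1 = select_edges(_edge_frame(weights), mix)
    net2 = select_edges(net1.edges, mix)
    pd.testing.assert_frame_equal(net1.edges, net2.edges)


# ---------------------------------------------------------------- topology


def _net_from_pairs(pairs, weights=None):
    weights = weights if weights is not None else [1.0] * len(pairs)
    frame = pd.DataFrame(
        {
            "gene_i": [a for a, _ in pairs],
            "gene_j": [b for _, b in pairs],
            "w_int": weights,
        }
    )
    from rtnets.network import GlobalNetwork

    nodes = sorted({g for p in pairs for g in p})
    return GlobalNetwork(nodes=nodes, edges=frame, mix=_mix())


def test_triangle_and_path_topology():
    tri = topology_metrics(_net_from_pairs([("a", "b"), ("b", "c"), ("a", "c")]))
    assert tri["density"] == 1.0 and tri["transitivity"] == 1.0
    assert tri["components"] == 1
    path = topology_metrics(_net_from_pairs([("a", "b"), ("b", "c")]))
    assert path["transitivity"] == 0.0


def test_topology_matches_networkx_oracle():
    rng = np.random.default_rng(13)
    g = nx.gnm_random_graph(30, 60, seed=13)
    pairs = [(f"n{a}", f"n{b}") for a, b in g.edges()]
    metrics = topology_metrics(_net_from_pairs(pairs))
    sub = g.subgraph([n for n in g if g.degree(n) > 0])
    assert metrics["transitivity"] == pytest.approx(nx.transitivity(sub))
    assert metrics["density"] == pytest.approx(nx.density(sub))
    assert metrics["components"] == nx.number_connected_components(sub)
    assert metrics["mean_degree"] == pytest.approx(
        np.mean([d for _, d in sub.degree()])
    )
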