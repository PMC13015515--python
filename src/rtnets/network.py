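"""Global gene-network construction.

Expression associations (Pearson ``r`` or precision-matrix partial
correlation ``rho``), replication-timing domain similarity, rank-based RT
profile correlation, and the integrated edge weight

    w_int = a * w_rna + b * s_rt_signed + gamma * norm(w_rna)

where ``s_rt_signed = 2 * s_rt - 1`` rescales the RT similarity to
[-1, 1] and ``norm(w_rna)`` is the population z-score of the surviving
association weights.  Pairs with ``|w_rna|`` below the correlation floor are
dropped before mixing; the mixed weights are thresholded at tau and cut to
the global top-K.  All orderings are deterministic (lexicographic gene-pair
tie-breaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import MixConfig
from .errors import EmptyNetworkError, InsufficientDataError, NumericalError


@dataclass
class CorrelationSet:
    """Pairwise gene associations with the matrices that produced them."""

    genes: list
    r: pd.DataFrame
    sigma: pd.DataFrame
    rho: Optional[pd.DataFrame] = None
    omega: Optional[pd.DataFrame] = None


def expression_correlations(
    expr: pd.DataFrame, min_samples: int = 5
) -> CorrelationSet:
    """Pairwise-complete Pearson correlations over a gene x sample matrix.

    Genes observed in fewer than ``min_samples`` samples or with zero
    variance are dropped (with a warning).
    """
    counts = expr.notna().sum(axis=1)
    keep = expr.loc[counts >= min_samples]
    var = keep.var(axis=1, ddof=0)
    degenerate = var.index[(var == 0) | var.isna()]
    if len(degenerate):
        warnings.warn(f"dropping zero-variance genes: {list(degenerate)}")
        keep = keep.drop(index=degenerate)
    if len(keep) < 2:
        raise InsufficientDataError("fewer than 2 usable genes for correlation")
    keep = keep.sort_index()
    r = keep.T.corr(method="pearson")
    r = (r + r.T) / 2.0
    np.fill_diagonal(r.values, 1.0)
    sigma = keep.T.cov()
    return CorrelationSet(genes=list(keep.index), r=r, sigma=sigma)


def partial_correlations(
    cset: CorrelationSet, ridge: Optional[float] = None
) -> CorrelationSet:
    """Fill rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj), Omega = Sigma^-1.

    ``ridge=None`` applies ``1e-4 * trace(Sigma)/p`` automatically when the
    covariance is ill-conditioned (p >= n territory); pass 0 to force plain
    inversion.  Diagonal set to 1 by convention, entries clipped to [-1, 1].
    """
    sigma = cset.sigma.to_numpy(dtype=float)
    p = sigma.shape[0]
    if ridge is None:
        cond = np.linalg.cond(sigma)
        ridge = 1e-4 * np.trace(sigma) / p if cond > 1e8 else 0.0
    reg = sigma + ridge * np.eye(p)
    try:
        omega = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"covariance singular even after ridge {ridge:.3g} "
            f"(condition estimate {np.linalg.cond(reg):.3g})"
        ) from exc
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    cset.rho = pd.DataFrame(rho, index=cset.genes, columns=cset.genes)
    cset.omega = pd.DataFrame(omega, index=cset.genes, columns=cset.genes)
    return cset


def rt_similarity(gene_rt: pd.Series) -> pd.DataFrame:
    """Replication-timing similarity s_ij = 1 - |RT_i - RT_j| / max spread.

    The pair attaining the maximum spread scores 0; identical RT scores 1.
    If all RT values coincide (zero spread) similarity degenerates to 1
    everywhere; pairs involving a missing RT get the neutral value 0.5.
    """
    vals = gene_rt.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise InsufficientDataError("need >= 2 genes with non-missing RT")
    spread = float(vals[ok].max() - vals[ok].min())
    n = len(vals)
    if spread == 0:
        s = np.ones((n, n))
    else:
        s = 1.0 - np.abs(vals[:, None] - vals[None, :]) / spread
    s = np.where(np.outer(ok, ok), s, 0.5)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=gene_rt.index, columns=gene_rt.index)


def rt_profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of rank-transformed per-sample RT profiles.

    Equivalent to Spearman correlation with average ranks for ties.
    Constant profiles have undefined correlation and are reported as 0
    (with a warning).
    """
    if profiles.shape[1] < 3:
        raise InsufficientDataError("need >= 3 samples for profile correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = profiles.T.corr(method="spearman")
    if corr.isna().any().any():
        warnings.warn("constant RT profiles: undefined correlations set to 0")
        corr = corr.fillna(0.0)
    arr = (corr.to_numpy() + corr.to_numpy().T) / 2.0
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)


def _pair_frame(genes: list) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(genes), k=1)
    return iu


def integrate_edges(
    cset: CorrelationSet,
    s_rt: Optional[pd.DataFrame],
    mix: MixConfig,
) -> pd.DataFrame:
    """Edge table with w_rna, s_rt, s_rt_signed, norm(w_rna) and w_int.

    ``w_rna`` is rho when ``mix.use_partial`` else r.  Pairs with
    ``|w_rna| < mix.min_abs_corr`` are dropped before mixing; the z-score
    ``norm(w_rna)`` is computed (population sd) over the surviving pairs.
    ``s_rt=None`` means no RT information: the neutral similarity 0.5
    (signed 0) is used.  Output rows are ordered lexicographically.
    """
    genes = sorted(cset.genes)
    w_src = cset.rho if mix.use_partial else cset.r
    if w_src is None:
        raise InsufficientDataError("partial correlations requested but absent")
    w = w_src.loc[genes, genes].to_numpy(dtype=float)
    if s_rt is None:
        s = np.full((len(genes), len(genes)), 0.5)
    else:
        s = s_rt.reindex(index=genes, columns=genes).to_numpy(dtype=float)
        s = np.where(np.isnan(s), 0.5, s)
    iu = _pair_frame(genes)
    w_rna = w[iu]
    s_pair = s[iu]
    keep = np.abs(w_rna) >= mix.min_abs_corr
    if not keep.any():
        raise EmptyNetworkError(
            f"no gene pair passes |w_rna| >= {mix.min_abs_corr}"
        )
    w_rna = w_rna[keep]
    s_pair = s_pair[keep]
    gi = np.asarray(genes, dtype=object)[iu[0][keep]]
    gj = np.asarray(genes, dtype=object)[iu[1][keep]]
    sd = w_rna.std(ddof=0)
    norm = (w_rna - w_rna.mean()) / sd if sd > 0 else np.zeros_like(w_rna)
    s_signed = 2.0 * s_pair - 1.0
    w_int = mix.alpha * w_rna + mix.beta_mix * s_signed + mix.gamma * norm
    edges = pd.DataFrame(
        {
            "gene_i": gi,
            "gene_j": gj,
            "w_rna": w_rna,
            "s_rt": s_pair,
            "s_rt_signed": s_signed,
            "w_rna_norm": norm,
            "w_int": w_int,
        }
    )
    return edges.sort_values(["gene_i", "gene_j"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class GlobalNetwork:
    """Thresholded, top-K-selected edge set over the gene universe."""

    nodes: list
    edges: pd.DataFrame
    mix: MixConfig

    @property
    def plot_edges(self) -> pd.DataFrame:
        ranked = self.edges.sort_values(
            ["w_int", "gene_i", "gene_j"], ascending=[False, True, True],
            kind="mergesort",
        )
        return ranked.head(self.mix.top_k_plot)


def select_edges(edges: pd.DataFrame, mix: MixConfig) -> GlobalNetwork:
    """Keep edges with w_int >= tau, then the global top-K by w_int.

    Ties at the K-th weight break lexicographically by gene pair.
    """
    passed = edges[edges["w_int"] >= mix.tau]
    if passed.empty:
        raise EmptyNetworkError(f"no edge reaches tau = {mix.tau}")
    ranked = passed.sort_values(
        ["w_int", "gene_i", "gene_j"], ascending=[False, True, True],
        kind="mergesort",
    )
    kept = ranked.head(mix.top_k_global)
    kept = kept.sort_values(["gene_i", "gene_j"], kind="mergesort").reset_index(
        drop=True
    )
    nodes = sorted(set(kept["gene_i"]) | set(kept["gene_j"]))
    return GlobalNetwork(nodes=nodes, edges=kept, mix=mix)


def topology_metrics(net: GlobalNetwork) -> dict:
    """Density, mean degree, transitivity and component count.

    Computed directly from adjacency sets (triangle counting for the global
    clustering coefficient, breadth-first search for components) on the
    node set spanned by the retained edges.
    """
    adj: dict = {}
    for row in net.edges.itertuples():
        adj.setdefault(row.gene_i, set()).add(row.gene_j)
        adj.setdefault(row.gene_j, set()).add(row.gene_i)
    nodes = sorted(adj)
    n = len(nodes)
    m = len(net.edges)
    if n < 2:
        raise EmptyNetworkError("network has fewer than 2 connected nodes")
    density = 2.0 * m / (n * (n - 1))
    mean_degree = 2.0 * m / n
    tri2 = 0  # each triangle counted once per edge => 3x total
    for row in net.edges.itertuples():
        tri2 += len(adj[row.gene_i] & adj[row.gene_j])
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes)
    transitivity = tri2 / triples if triples > 0 else 0.0
    seen: set = set()
    components = 0
    for v in nodes:
        if v in seen:
            continue
        components += 1
        stack = [v]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u] - seen)
    return {
        "n_nodes": n,
        "n_edges": m,
        "density": density,
        "mean_degree": mean_degree,
        "transitivity": transitivity,
        "components": components,
    }
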