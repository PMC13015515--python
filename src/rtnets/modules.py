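"""Gene modules, per-patient module scores and subtype prediction.

The retained global network is partitioned into gene modules by greedy
modularity maximization on the weighted graph (negative weights floored at
zero for clustering only).  Each patient's module score is the mean of that
patient's individualized edge weights over the module's internal edges:

    m_k(q) = mean over (i,j) in E_k of e_ij(q)

Subtype is read out with a penalized logistic model p_basal = sigma(b0 +
sum_k b_k m_k) under stratified cross-validation, and each raw module score
is also assessed directly by a rank-based (Mann-Whitney) AUC.  Optional
morphology embeddings modulate scores multiplicatively through a sigmoid
gate learned from the embeddings within CV training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import InsufficientDataError, SchemaError
from .network import GlobalNetwork


@dataclass
class Module:
    module_id: str
    genes: list
    edges: list  # (gene_i, gene_j) pairs internal to the module


@dataclass
class ModuleSet:
    modules: list
    unassigned: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.modules)

    def by_id(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


def detect_modules(net: GlobalNetwork, seed: int = 1337) -> ModuleSet:
    """Greedy-modularity communities on the retained weighted graph.

    Deterministic for a fixed input network (nodes and edges are inserted
    in sorted order; ``seed`` is accepted for interface stability).
    Communities are ordered by descending size with lexicographic
    tie-breaks and labeled module_0, module_1, ...; singletons are pooled
    into an unassigned set excluded from scoring.
    """
    del seed  # greedy modularity is deterministic given sorted insertion
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    for row in net.edges.itertuples():
        g.add_edge(row.gene_i, row.gene_j, weight=max(float(row.w_int), 0.0))
    if g.number_of_edges() == 0:
        return ModuleSet(
            modules=[Module("module_0", sorted(net.nodes), [])], unassigned=[]
        )
    communities = nx.algorithms.community.greedy_modularity_communities(
        g, weight="weight"
    )
    comms = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    modules = []
    unassigned = []
    for genes in comms:
        if len(genes) < 2:
            unassigned.extend(genes)
            continue
        gene_set = set(genes)
        edges = [
            (row.gene_i, row.gene_j)
            for row in net.edges.itertuples()
            if row.gene_i in gene_set and row.gene_j in gene_set
        ]
        modules.append(Module(f"module_{len(modules)}", genes, edges))
    return ModuleSet(modules=modules, unassigned=sorted(unassigned))


@dataclass
class ModuleScoreMatrix:
    """Samples x modules mean intra-module individualized edge weights."""

    scores: pd.DataFrame  # samples x modules
    coverage: pd.DataFrame  # fraction of non-missing edges behind each score


def module_scores(lion, mods: ModuleSet) -> ModuleScoreMatrix:
    """Mean of e_ij(q) over each module's internal edges, per sample.

    Missing edges are excluded from both numerator and denominator; the
    coverage matrix reports the fraction used.  Modules with no internal
    edges are excluded.
    """
    pair_pos = {tuple(p): i for i, p in enumerate(lion.edge_index)}
    cols = {}
    cov = {}
    for mod in mods:
        idx = [pair_pos[p] for p in mod.edges if tuple(p) in pair_pos]
        if not idx:
            continue
        block = lion.e_q.to_numpy()[idx, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cols[mod.module_id] = np.nanmean(block, axis=0)
        cov[mod.module_id] = np.mean(~np.isnan(block), axis=0)
    if not cols:
        raise InsufficientDataError("no module has scoreable edges")
    scores = pd.DataFrame(cols, index=lion.sample_ids)
    coverage = pd.DataFrame(cov, index=lion.sample_ids)
    return ModuleScoreMatrix(scores=scores, coverage=coverage)


@dataclass
class SubtypeModel:
    beta0: float
    betas: dict
    threshold: float = 0.5

    def predict_proba(self, scores: pd.DataFrame) -> pd.Series:
        z = self.beta0 + sum(
            coef * scores[mod] for mod, coef in self.betas.items()
        )
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SubtypeResult:
    model: SubtypeModel
    p_hat: pd.Series  # out-of-fold probabilities
    y_hat: pd.Series
    auc: float
    n_dropped: int


def _binary_labels(labels: pd.Series, positive: str) -> pd.Series:
    lab = labels.str.lower()
    bad = set(lab.unique()) - {"basal", "classical"}
    if bad:
        raise SchemaError(f"unknown subtype labels: {sorted(bad)}")
    return (lab == positive).astype(int)


def rank_auc(score: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise InsufficientDataError("AUC needs both classes present")
    ranks = rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fit_subtype(
    scores: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 5,
    seed: int = 1337,
    l2_c: float = 10.0,
    positive_class: str = "basal",
) -> SubtypeResult:
    """L2-penalized logistic subtype model with stratified CV AUC.

    Out-of-fold probabilities from a seeded stratified k-fold are pooled
    into a single AUC; the reported coefficients come from a final fit on
    all samples.  Rows with missing scores are dropped (count reported).
    """
    mask = scores.notna().all(axis=1)
    n_dropped = int((~mask).sum())
    x_df = scores.loc[mask]
    y = _binary_labels(labels.reindex(x_df.index), positive_class)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise InsufficientDataError("need >= 2 samples per class")
    if min(int(y.sum()), int((1 - y).sum())) < cv_folds:
        raise InsufficientDataError(
            "a CV fold would contain a single class; use fewer, larger folds"
        )
    x = x_df.to_numpy()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    p_hat = np.empty(len(y))
    for train, test in skf.split(x, y):
        clf = LogisticRegression(C=l2_c, max_iter=2000)
        clf.fit(x[train], y.iloc[train])
        p_hat[test] = clf.predict_proba(x[test])[:, 1]
    auc = rank_auc(p_hat, y.to_numpy())
    final = LogisticRegression(C=l2_c, max_iter=2000).fit(x, y)
    model = SubtypeModel(
        beta0=float(final.intercept_[0]),
        betas={m: float(c) for m, c in zip(x_df.columns, final.coef_[0])},
    )
    p_series = pd.Series(p_hat, index=x_df.index, name="p_hat")
    y_hat = (p_series >= model.threshold).astype(int).rename("y_hat")
    return SubtypeResult(
        model=model, p_hat=p_series, y_hat=y_hat, auc=auc, n_dropped=n_dropped
    )


def per_module_auc(
    scores: pd.DataFrame,
    labels: pd.Series,
    mods: ModuleSet | None = None,
    positive_class: str = "basal",
) -> pd.DataFrame:
    """Rank-based AUC of each raw module score against the subtype labels.

    No model fitting: the score itself is the ranking statistic, so the
    result is invariant to any strictly monotone transform.  The AUC in the
    opposite labeling direction is exactly 1 - AUC.
    """
    mask = scores.notna().all(axis=1)
    y = _binary_labels(labels.reindex(scores.index[mask]), positive_class)
    rows = []
    for mod in scores.columns:
        auc = rank_auc(scores.loc[mask, mod].to_numpy(), y.to_numpy())
        n_genes = len(mods.by_id(mod).genes) if mods is not None else np.nan
        rows.append((mod, n_genes, auc))
    return pd.DataFrame(rows, columns=["module", "n_genes", "auc"])


def morph_modulate(
    scores: ModuleScoreMatrix,
    embeddings: pd.DataFrame,
    labels: pd.Series,
    seed: int = 1337,
    cv_folds: int = 5,
    l2_c: float = 0.1,
    gate: str = "sigmoid_mult",
) -> ModuleScoreMatrix:
    """Weight module activation by a morphology gate g(q) = sigma(theta' f).

    ``theta`` is fit by L2-penalized logistic regression of the subtype
    label on cohort-standardized embeddings, within CV training folds only
    (each sample's gate comes from the fold that held it out, avoiding
    leakage).  The penalty is deliberately strong (default C=0.1) so that
    uninformative embeddings shrink the gate toward a constant and leave
    the module scores essentially unchanged.  One shared theta serves all modules; the modulated score is
    m'_k(q) = m_k(q) * g(q).  ``gate="off"`` returns the scores unchanged
    (identity gate g = 1).
    """
    if gate == "off":
        return ModuleScoreMatrix(scores.scores.copy(), scores.coverage.copy())
    if gate != "sigmoid_mult":
        raise ValueError(f"unknown morphology gate {gate!r}")
    samples = list(scores.scores.index)
    missing = [s for s in samples if s not in embeddings.index]
    if missing:
        raise SchemaError(f"samples without embeddings: {missing}")
    emb = embeddings.loc[samples].to_numpy(dtype=float)
    if emb.ndim != 2 or emb.shape[0] != len(samples):
        raise SchemaError("embedding matrix shape mismatch")
    mu = emb.mean(axis=0)
    sd = emb.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    f = (emb - mu) / sd
    y = _binary_labels(labels.reindex(samples), "basal")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    g = np.empty(len(samples))
    for train, test in skf.split(f, y):
        clf = LogisticRegression(C=l2_c, max_iter=2000)
        clf.fit(f[train], y.iloc[train])
        g[test] = clf.predict_proba(f[test])[:, 1]
    gated = scores.scores.mul(pd.Series(g, index=samples), axis=0)
    return ModuleScoreMatrix(scores=gated, coverage=scores.coverage.copy())
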