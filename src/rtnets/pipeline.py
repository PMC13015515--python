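"""End-to-end orchestration: I/O glue, condition presets, run reports.

A *condition* names a network recipe:

* ``RNA`` — pure expression-correlation network (mix a=1, b=0, gamma=0).
* ``RT`` — rank-correlation network over per-sample gene RT profiles.
* ``RT_RNA`` — integrated edge weights (default mix a=1, b=0.5, gamma=0.5).
* ``RT_RNA_PCORR`` — integrated, with partial correlations as w_rna.
* ``MORPH_RNA`` — the RNA network with morphology-gated module scores.

Each run builds the global network, freezes its pair set, derives LIONESS
per-patient networks, detects modules, scores them per patient, fits the
subtype readout, and writes every artifact table plus a machine-readable
report with content hashes (identical config => identical hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import MixConfig, RunConfig
from .errors import EmptyNetworkError, SchemaError
from .lioness import lioness_networks
from .methylation import compute_rt_assets, load_beta_matrix, load_manifest
from .modules import (
    ModuleScoreMatrix,
    detect_modules,
    fit_subtype,
    module_scores,
    morph_modulate,
    per_module_auc,
)
from .network import (
    CorrelationSet,
    expression_correlations,
    integrate_edges,
    partial_correlations,
    rt_profile_correlation,
    rt_similarity,
    select_edges,
    topology_metrics,
)
from .synthetic import WindowGrid

logger = logging.getLogger("rtnets")

CONDITIONS = ("RNA", "RT", "RT_RNA", "MORPH_RNA", "RT_RNA_PCORR")


# ---------------------------------------------------------------- file I/O


def read_expression(path) -> pd.DataFrame:
    """Gene x sample TSV; first column gene ids, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate gene ids: {dupes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:3]
            raise SchemaError(
                f"non-numeric expression values in column {col!r}, "
                f"e.g. rows {list(bad)}"
            )
    return df


def read_labels(path) -> pd.Series:
    """sample_id,subtype CSV; subtype in {basal, classical}, any case."""
    df = pd.read_csv(path, dtype=str)
    if not {"sample_id", "subtype"} <= set(df.columns):
        raise SchemaError("labels file needs columns sample_id, subtype")
    sub = df["subtype"].str.strip().str.lower()
    bad = sorted(set(sub.unique()) - {"basal", "classical"})
    if bad:
        raise SchemaError(f"unknown subtype tokens: {bad}")
    labels = pd.Series(sub.to_numpy(), index=df["sample_id"].str.strip(), name="subtype")
    logger.info(
        "labels: %d basal / %d classical",
        (labels == "basal").sum(),
        (labels == "classical").sum(),
    )
    return labels


def read_embeddings(path) -> pd.DataFrame:
    """sample_id, e1..eD TSV of patient-level morphology embeddings."""
    return pd.read_csv(path, sep="\t", index_col=0)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ------------------------------------------------------ condition plumbing


def condition_mix(base: MixConfig, condition: str) -> MixConfig:
    if condition in ("RNA", "MORPH_RNA", "RT"):
        return dataclasses.replace(
            base, alpha=1.0, beta_mix=0.0, gamma=0.0, use_partial=False
        )
    if condition == "RT_RNA":
        return dataclasses.replace(base, use_partial=False)
    if condition == "RT_RNA_PCORR":
        return dataclasses.replace(base, use_partial=True)
    raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")


def pair_weight_fn(
    expr: pd.DataFrame,
    pairs: list,
    mix: MixConfig,
    rt_profiles: Optional[pd.DataFrame] = None,
):
    """Edge function over a frozen pair set, for LIONESS individualization.

    Given a sample-subset expression matrix it recomputes the pairwise
    associations, the RT-domain similarity (from the subset-mean gene RT
    profile, when provided) and the z-normalization over the frozen pair
    set, and mixes them with the configured (a, b, gamma).  Genes falling
    below ``min_samples`` non-missing values in the subset yield NaN edges.
    """
    gene_list = sorted(expr.index)
    pos = {g: i for i, g in enumerate(gene_list)}
    ii = np.array([pos[a] for a, _ in pairs])
    jj = np.array([pos[b] for _, b in pairs])

    def fn(sub: pd.DataFrame) -> np.ndarray:
        x = sub.loc[gene_list]
        enough = x.notna().sum(axis=1).to_numpy() >= mix.min_samples
        var_ok = x.var(axis=1, ddof=0).to_numpy() > 0
        usable = enough & var_ok
        r = x.T.corr(method="pearson").to_numpy()
        w = r[ii, jj]
        w[~(usable[ii] & usable[jj])] = np.nan
        if mix.beta_mix != 0.0 and rt_profiles is not None:
            gene_rt = rt_profiles.reindex(gene_list)[list(sub.columns)].mean(axis=1)
            s = rt_similarity(gene_rt).to_numpy()[ii, jj]
        else:
            s = np.full(len(w), 0.5)
        ok = ~np.isnan(w)
        if mix.gamma != 0.0 and ok.any():
            sd = w[ok].std(ddof=0)
            norm = np.full(len(w), np.nan)
            norm[ok] = (w[ok] - w[ok].mean()) / sd if sd > 0 else 0.0
        else:
            norm = np.zeros(len(w))
        return mix.alpha * w + mix.beta_mix * (2.0 * s - 1.0) + mix.gamma * norm

    return fn


def rt_pair_weight_fn(profiles: pd.DataFrame, pairs: list):
    """Spearman edge function over frozen pairs of gene RT profiles."""
    gene_list = sorted(profiles.index)
    pos = {g: i for i, g in enumerate(gene_list)}
    ii = np.array([pos[a] for a, _ in pairs])
    jj = np.array([pos[b] for _, b in pairs])

    def fn(sub: pd.DataFrame) -> np.ndarray:
        corr = rt_profile_correlation(sub.loc[gene_list]).to_numpy()
        return corr[ii, jj]

    return fn


def build_global_network(
    expr: pd.DataFrame,
    mix: MixConfig,
    condition: str,
    rt_profiles: Optional[pd.DataFrame] = None,
):
    """Construct the selected global network for a condition.

    Returns (CorrelationSet-or-None, edge table, GlobalNetwork).  For the
    RT condition the association source is the rank correlation of RT
    profiles pushed through the same filter/threshold/top-K machinery.
    """
    cmix = condition_mix(mix, condition)
    if condition == "RT":
        if rt_profiles is None:
            raise SchemaError("condition RT requires methylation-derived profiles")
        prof_corr = rt_profile_correlation(rt_profiles)
        genes = list(prof_corr.index)
        cset = CorrelationSet(genes=genes, r=prof_corr, sigma=prof_corr)
        edges = integrate_edges(cset, None, cmix)
        return cset, edges, select_edges(edges, cmix)
    cset = expression_correlations(expr, cmix.min_samples)
    if cmix.use_partial:
        cset = partial_correlations(cset)
    s_rt = None
    if cmix.beta_mix != 0.0 and rt_profiles is not None:
        gene_rt = rt_profiles.reindex(cset.genes).mean(axis=1)
        s_rt = rt_similarity(gene_rt)
    edges = integrate_edges(cset, s_rt, cmix)
    return cset, edges, select_edges(edges, cmix)


def individualize(
    expr: pd.DataFrame,
    net,
    mix: MixConfig,
    condition: str,
    rt_profiles: Optional[pd.DataFrame] = None,
):
    """LIONESS over the frozen pair set of a selected global network."""
    cmix = condition_mix(mix, condition)
    pairs = list(zip(net.edges["gene_i"], net.edges["gene_j"]))
    if condition == "RT":
        fn = rt_pair_weight_fn(rt_profiles, pairs)
        data = rt_profiles
    else:
        fn = pair_weight_fn(expr, pairs, cmix, rt_profiles=rt_profiles)
        data = expr
    return lioness_networks(fn, data, pairs)


# ------------------------------------------------------------ run wrapper


def _load_rt_assets(config: RunConfig, genes):
    manifest = load_manifest(config.manifest)
    meth_dir = Path(config.methylation_dir)
    files = sorted(p for p in meth_dir.iterdir() if p.suffix in (".txt", ".csv", ".tsv"))
    betas = load_beta_matrix(files, manifest)
    sizes = (
        manifest.groupby("chrom")["pos"].max().add(config.rt.window_bp).astype(int)
    )
    grid = WindowGrid.uniform(sizes.to_dict(), config.rt.window_bp)
    return manifest, compute_rt_assets(
        betas, manifest, grid, rt_cfg=config.rt, genes=genes
    )


def run(config: RunConfig, condition: str) -> dict:
    """Execute the full stage graph for one condition and write artifacts."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    for name in ("expression", "labels"):
        if getattr(config, name) is None:
            raise SchemaError(f"condition {condition} requires a {name} path")
    needs_rt = condition in ("RT", "RT_RNA", "RT_RNA_PCORR")
    if needs_rt and (config.methylation_dir is None or config.manifest is None):
        raise SchemaError(
            f"condition {condition} requires methylation_dir and manifest paths"
        )
    if condition == "MORPH_RNA" and config.embeddings is None:
        raise SchemaError("condition MORPH_RNA requires an embeddings path")

    out = Path(config.out_dir) / condition
    out.mkdir(parents=True, exist_ok=True)
    expr = read_expression(config.expression)
    labels = read_labels(config.labels)
    common = [s for s in expr.columns if s in labels.index]
    expr = expr[common]
    labels = labels.reindex(common)

    rt_profiles = None
    summary_df = None
    if needs_rt:
        manifest, (windows, domains, summary_df, rt_profiles) = _load_rt_assets(
            config, list(expr.index)
        )
        rt_profiles = rt_profiles[common]
        _write_rt_artifacts(out, windows, domains, summary_df)

    report: dict = {
        "condition": condition,
        "seed": config.seed,
        "parameters": dataclasses.asdict(condition_mix(config.mix, condition)),
        "rt_parameters": dataclasses.asdict(config.rt),
        "n_samples": len(common),
        "n_genes": int(expr.shape[0]),
    }
    try:
        _, edges, net = build_global_network(
            expr, config.mix, condition, rt_profiles=rt_profiles
        )
    except EmptyNetworkError as exc:
        # mirrors conditions whose association source cannot produce edges
        report.update(
            {"status": "empty_network", "reason": str(exc), "metrics": None}
        )
        _finish_report(out, report)
        return report

    lion = individualize(expr, net, config.mix, condition, rt_profiles=rt_profiles)
    mods = detect_modules(net, seed=config.seed)
    scores = module_scores(lion, mods)
    if condition == "MORPH_RNA":
        emb = read_embeddings(config.embeddings).reindex(common)
        scores = morph_modulate(
            scores,
            emb,
            labels,
            seed=config.seed,
            cv_folds=config.model.cv_folds,
            gate=config.model.morph_gate,
        )
    fit = fit_subtype(
        scores.scores,
        labels,
        cv_folds=config.model.cv_folds,
        seed=config.seed,
        l2_c=config.model.l2_c,
        positive_class=config.model.positive_class,
    )
    pm_auc = per_module_auc(
        scores.scores, labels, mods, positive_class=config.model.positive_class
    )

    report.update(
        {
            "status": "ok",
            "metrics": topology_metrics(net),
            "subtype_auc": fit.auc,
            "per_module_auc": pm_auc.to_dict(orient="records"),
            "module_sizes": {m.module_id: len(m.genes) for m in mods},
        }
    )
    _write_network_artifacts(out, net, lion, mods, scores, fit, pm_auc)
    _finish_report(out, report)
    return report


def _write_rt_artifacts(out: Path, windows, domains, summary_df) -> None:
    tracks = out / "rt_tracks"
    tracks.mkdir(exist_ok=True)
    for sample, win in windows.items():
        track = win.dropna(subset=["rt"])[["chrom", "start", "end", "rt"]]
        track.to_csv(
            tracks / f"{sample}.bedgraph",
            sep="\t",
            header=False,
            index=False,
            float_format="%.6f",
        )
    pd.concat(
        {s: d.set_index("domain_id")["rt_domain"] for s, d in domains.items()},
        axis=1,
    ).to_csv(out / "domains.tsv", sep="\t", float_format="%.6f")
    summary_df.to_csv(out / "sample_rt_summary.csv", float_format="%.6f")


def _write_network_artifacts(out: Path, net, lion, mods, scores, fit, pm_auc) -> None:
    net.edges.to_csv(out / "edges.tsv", sep="\t", index=False, float_format="%.8f")
    pd.DataFrame([topology_metrics(net)]).to_csv(out / "topology.csv", index=False)
    pd.DataFrame(
        [(m.module_id, g) for m in mods for g in m.genes],
        columns=["module_id", "gene"],
    ).to_csv(out / "modules.tsv", sep="\t", index=False)
    wide = lion.e_q.copy()
    wide.index = [f"{a}|{b}" for a, b in lion.edge_index]
    wide.to_csv(out / "lioness_wide.tsv", sep="\t", float_format="%.8f")
    long = wide.stack().rename("e_q").rename_axis(["edge", "sample"]).reset_index()
    long.to_csv(out / "lioness_long.tsv", sep="\t", index=False, float_format="%.8f")
    pd.DataFrame(
        {"missing_edges": lion.e_q.isna().sum(axis=0)}
    ).rename_axis("sample").to_csv(out / "lioness_missing.csv")
    scores.scores.rename_axis("sample").to_csv(
        out / "module_scores.tsv", sep="\t", float_format="%.8f"
    )
    pm_auc.to_csv(out / "per_module_auc.csv", index=False, float_format="%.6f")
    (out / "model.json").write_text(
        json.dumps(
            {"beta0": fit.model.beta0, "betas": fit.model.betas, "auc": fit.auc},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    plot = net.plot_edges
    node_link = {
        "nodes": [{"id": g} for g in sorted(set(plot["gene_i"]) | set(plot["gene_j"]))],
        "links": [
            {"source": r.gene_i, "target": r.gene_j, "weight": round(float(r.w_int), 8)}
            for r in plot.itertuples()
        ],
    }
    (out / "network_top.json").write_text(
        json.dumps(node_link, indent=2, sort_keys=True) + "\n"
    )


def _finish_report(out: Path, report: dict) -> None:
    outputs = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "report.json":
            outputs[str(path.relative_to(out))] = _sha256(path)
    report["outputs"] = outputs
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )


# ------------------------------------------------------- validation presets


def subtype_metric_fn(scores: pd.DataFrame, model_cfg, seed: int):
    """Metric closure for the permutation null: labels -> {"auc": ...}.

    The network and module scores do not depend on subtype labels, so a
    label shuffle leaves the graph fixed and moves only the subtype
    readout; the closure recomputes the cross-validated AUC per shuffle.
    """

    def fn(labels: pd.Series) -> dict:
        fit = fit_subtype(
            scores,
            labels,
            cv_folds=model_cfg.cv_folds,
            seed=seed,
            l2_c=model_cfg.l2_c,
            positive_class=model_cfg.positive_class,
        )
        return {"auc": fit.auc}

    return fn


def network_builder(mix: MixConfig, condition: str, rt_profiles=None):
    """Cohort-subset -> selected edge table, for bootstrap stability."""

    def build(sub_expr: pd.DataFrame) -> pd.DataFrame:
        prof = rt_profiles[list(sub_expr.columns)] if rt_profiles is not None else None
        _, _, net = build_global_network(sub_expr, mix, condition, rt_profiles=prof)
        return net.edges

    return build


def grid_evaluator(
    expr: pd.DataFrame,
    labels: pd.Series,
    base_mix: MixConfig,
    model_cfg,
    seed: int,
    rt_profiles=None,
):
    """Cell evaluator: full network -> LIONESS -> modules -> AUC pipeline."""

    def evaluate(a: float, b: float, g: float) -> dict:
        mix = dataclasses.replace(base_mix, alpha=a, beta_mix=b, gamma=g)
        _, _, net = build_global_network(expr, mix, "RT_RNA", rt_profiles=rt_profiles)
        lion = individualize(expr, net, mix, "RT_RNA", rt_profiles=rt_profiles)
        mods = detect_modules(net, seed=seed)
        scores = module_scores(lion, mods)
        fit = fit_subtype(
            scores.scores,
            labels,
            cv_folds=model_cfg.cv_folds,
            seed=seed,
            l2_c=model_cfg.l2_c,
            positive_class=model_cfg.positive_class,
        )
        out = topology_metrics(net)
        out["auc"] = fit.auc
        return out

    return evaluate
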