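"""Promoter methylation ingestion and replication-timing proxies.

Heterogeneous per-sample beta-value text files are parsed with automatic
column detection (the probe column is recognized by its match rate against
the manifest), promoter probes (TSS200 / TSS1500 / 5'UTR / First Exon) are
averaged per gene, and window-level methylation is inverted into a
replication-timing (RT) proxy:

    median beta per genomic window  ->  centered rolling-mean smoothing
    (within chromosome)  ->  genome-wide z-score  ->  sign inversion

so hypermethylated windows receive a low RT proxy (late replication).
Windows are grouped into fixed-span domains whose RT is the length-weighted
mean of member windows; per-sample summaries report the length-weighted mean
RT and the length-weighted late fraction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RTConfig
from .errors import DegenerateRTWarning, FormatError, InsufficientDataError
from .synthetic import WindowGrid

PROMOTER_CLASSES = {"TSS200", "TSS1500", "5UTR", "FirstExon"}

_CLASS_ALIASES = {
    "TSS200": "TSS200",
    "TSS1500": "TSS1500",
    "5UTR": "5UTR",
    "5'UTR": "5UTR",
    "FIRSTEXON": "FirstExon",
    "FIRST EXON": "FirstExon",
    "1STEXON": "FirstExon",
}


def _normalize_region_class(raw: str) -> str:
    key = str(raw).strip().upper().replace("_", " ")
    key = _CLASS_ALIASES.get(key.replace(" ", ""), _CLASS_ALIASES.get(key, None))
    return key if key is not None else "other"


def _normalize_probe(token: str) -> str:
    return token.strip().strip("'\"")


def load_manifest(path) -> pd.DataFrame:
    """Read a probe manifest CSV (probe_id, gene, region_class, chrom, pos).

    The gene field may hold several semicolon-separated genes (multi-gene
    probes); it is parsed into a list.  Region classes are normalized to
    {TSS200, TSS1500, 5UTR, FirstExon, other}.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"probe_id", "gene", "region_class", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    df["probe_id"] = df["probe_id"].map(_normalize_probe)
    df["genes"] = df["gene"].map(
        lambda s: [g.strip() for g in re.split("[;,]", s) if g.strip()]
    )
    df["region_class"] = df["region_class"].map(_normalize_region_class)
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 0).any():
        raise FormatError("manifest contains negative probe positions")
    return df[["probe_id", "genes", "region_class", "chrom", "pos"]]


def parse_beta_file(path, manifest_probes) -> dict[str, float]:
    """Parse one beta-value file of unknown layout into a probe -> beta map.

    The delimiter (comma or tab) is sniffed, the probe column is the one
    whose entries best match the manifest probe set (requiring >= 50% match
    rate), and the beta column is the best-parsing numeric column among the
    rest.  Header rows fall out naturally as non-numeric entries.  Betas are
    clipped to [0, 1]; non-numeric values are dropped.
    """
    probe_set = set(manifest_probes)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty methylation file")
    delim = "\t" if "\t" in lines[0] else ","
    rows = [ln.split(delim) for ln in lines]
    n_cols = max(len(r) for r in rows)
    if n_cols < 2:
        raise FormatError(f"{path}: fewer than 2 columns detected")

    def col(i):
        return [_normalize_probe(r[i]) if i < len(r) else "" for r in rows]

    match_rates = []
    for i in range(n_cols):
        vals = col(i)
        match_rates.append(sum(v in probe_set for v in vals) / len(vals))
    probe_col = int(np.argmax(match_rates))
    if match_rates[probe_col] < 0.5:
        raise FormatError(
            f"{path}: no column matches >= 50% of manifest probes "
            f"(best rate {match_rates[probe_col]:.2f})"
        )

    def numeric_rate(i):
        ok = 0
        for v in col(i):
            try:
                float(v)
                ok += 1
            except ValueError:
                pass
        return ok / len(rows)

    candidates = [i for i in range(n_cols) if i != probe_col]
    rates = [numeric_rate(i) for i in candidates]
    beta_col = candidates[int(np.argmax(rates))]
    if max(rates) < 0.5:
        raise FormatError(f"{path}: no numeric beta column found")

    out: dict[str, float] = {}
    for r in rows:
        if len(r) <= max(probe_col, beta_col):
            continue
        probe = _normalize_probe(r[probe_col])
        try:
            val = float(r[beta_col])
        except ValueError:
            continue
        out[probe] = float(np.clip(val, 0.0, 1.0))
    return out


@dataclass
class BetaMatrix:
    """Probe x sample beta values in [0, 1] (NaN where a probe is absent)."""

    beta: pd.DataFrame

    @property
    def probe_ids(self):
        return list(self.beta.index)

    @property
    def sample_ids(self):
        return list(self.beta.columns)


def load_beta_matrix(paths, manifest: pd.DataFrame) -> BetaMatrix:
    """Assemble a BetaMatrix from per-sample files (sample id = file stem)."""
    from pathlib import Path

    probe_ids = manifest["probe_id"].tolist()
    cols = {}
    for path in sorted(str(p) for p in paths):
        sample = Path(path).stem
        betas = parse_beta_file(path, probe_ids)
        cols[sample] = pd.Series(betas)
    beta = pd.DataFrame(cols).reindex(probe_ids)
    return BetaMatrix(beta)


@dataclass
class PromoterMethylation:
    """Per-gene promoter methylation: means, cross-sample z-scores, states."""

    mean_beta: pd.DataFrame  # genes x samples
    zscore: pd.DataFrame
    state: pd.DataFrame


def promoter_aggregate(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    hypo_thresh: float = -1.0,
    hyper_thresh: float = 1.0,
) -> PromoterMethylation:
    """Average promoter-class probes per gene, then z-score across samples.

    Multi-gene probes contribute to every mapped gene.  Genes with no
    promoter probe are absent from the output.  Zero-variance genes get
    z-score 0 (state baseline) rather than NaN.
    """
    prom = manifest[manifest["region_class"].isin(PROMOTER_CLASSES)]
    pairs = prom.explode("genes").dropna(subset=["genes"])
    pairs = pairs[pairs["genes"] != ""]
    if pairs.empty:
        raise InsufficientDataError("manifest contains no usable promoter probes")
    merged = betas.beta.reindex(pairs["probe_id"])
    merged.index = pairs["genes"].to_numpy()
    mean_beta = merged.groupby(level=0).mean().sort_index()
    mean_beta = mean_beta.dropna(how="all")
    if mean_beta.empty:
        raise InsufficientDataError("no promoter probe carries beta values")

    mu = mean_beta.mean(axis=1)
    sd = mean_beta.std(axis=1, ddof=0)
    z = mean_beta.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    state = call_states(z, hypo_thresh, hyper_thresh)
    return PromoterMethylation(mean_beta=mean_beta, zscore=z, state=state)


def call_states(
    zscore: pd.DataFrame, hypo_thresh: float = -1.0, hyper_thresh: float = 1.0
) -> pd.DataFrame:
    """Classify z-scores into hypo / baseline / hyper at fixed thresholds."""
    if not hypo_thresh < hyper_thresh:
        raise ValueError("hypo_thresh must be < hyper_thresh")
    z = zscore.to_numpy()
    out = np.where(z <= hypo_thresh, "hypo", np.where(z >= hyper_thresh, "hyper", "baseline"))
    return pd.DataFrame(out, index=zscore.index, columns=zscore.columns)


def _assign_windows(manifest: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    """Window row index (into grid.windows) per probe; -1 when unassigned."""
    win = grid.windows
    out = np.full(len(manifest), -1, dtype=int)
    for chrom, grp in win.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        rows = grp.index.to_numpy()
        mask = (manifest["chrom"] == chrom).to_numpy()
        pos = manifest.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        assigned = np.where(ok, rows[np.clip(idx, 0, len(rows) - 1)], -1)
        out[mask] = assigned
    return out


def bin_and_smooth(
    sample_betas: pd.Series,
    manifest: pd.DataFrame,
    grid: WindowGrid,
    smoothing_width: int = 3,
) -> pd.DataFrame:
    """Median beta per window, smoothed per chromosome.

    Returns one row per window with columns chrom, start, end, length_bp,
    median_beta and smoothed.  Empty windows carry NaN and stay NaN after
    smoothing (the rolling mean skips missing neighbors; window edges use
    truncated, shorter means).  Chromosome boundaries are never mixed.
    """
    win = grid.windows.copy()
    win["length_bp"] = win["end"] - win["start"]
    probe_win = _assign_windows(manifest, grid)
    vals = sample_betas.reindex(manifest["probe_id"]).to_numpy(dtype=float)
    med = pd.Series(vals).groupby(probe_win).median()
    med = med[med.index >= 0]
    win["median_beta"] = med.reindex(win.index)

    smoothed = np.full(len(win), np.nan)
    for chrom, grp in win.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        series = grp["median_beta"]
        if series.isna().all():
            warnings.warn(f"{chrom}: all windows empty, chromosome skipped")
            continue
        sm = series.rolling(smoothing_width, center=True, min_periods=1).mean()
        sm = sm.where(series.notna())  # empty windows stay missing
        smoothed[win.index.get_indexer(grp.index)] = sm.to_numpy()
    win["smoothed"] = smoothed
    return win


def methylation_to_rt(windows: pd.DataFrame) -> pd.DataFrame:
    """RT proxy: negative genome-wide z-score of smoothed window methylation.

    z uses the population (n) denominator over all non-missing windows of
    the sample.  Zero variance across windows degenerates to rt = 0
    everywhere (with a warning).
    """
    win = windows.copy()
    vals = win["smoothed"].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise InsufficientDataError("need >= 2 non-missing windows for z-scoring")
    mu = vals[ok].mean()
    sd = vals[ok].std(ddof=0)
    rt = np.full(len(win), np.nan)
    if sd == 0:
        warnings.warn(
            "zero variance across windows; RT proxy set to 0", DegenerateRTWarning
        )
        rt[ok] = 0.0
    else:
        rt[ok] = -(vals[ok] - mu) / sd
    win["rt"] = rt
    return win


def aggregate_domains(windows: pd.DataFrame, domain_span_bp: int) -> pd.DataFrame:
    """Group contiguous windows into fixed spans; RT is length-weighted.

    Domains with only missing windows are emitted with NaN RT (excluded from
    downstream similarity computations).
    """
    if domain_span_bp < (windows["end"] - windows["start"]).min():
        raise ValueError("domain span must be >= window size")
    win = windows.copy()
    win["domain_idx"] = win["start"] // domain_span_bp
    rows = []
    for (chrom, didx), grp in win.groupby(["chrom", "domain_idx"], sort=True):
        ok = grp["rt"].notna()
        if ok.any():
            lw = grp.loc[ok, "length_bp"].to_numpy(dtype=float)
            rt = float((lw * grp.loc[ok, "rt"].to_numpy()).sum() / lw.sum())
        else:
            rt = np.nan
        rows.append(
            (
                f"{chrom}:{int(didx)}",
                chrom,
                int(grp["start"].min()),
                int(grp["end"].max()),
                rt,
            )
        )
    return pd.DataFrame(rows, columns=["domain_id", "chrom", "start", "end", "rt_domain"])


@dataclass
class SampleRTSummary:
    sample_id: str
    rt_mean: float
    frac_late: float


def sample_summary(
    windows: pd.DataFrame, sample_id: str = "", late_sign: str = "negative"
) -> SampleRTSummary:
    """Length-weighted mean RT and late fraction over non-missing windows.

    ``late_sign="negative"`` calls a window late when its RT proxy is below
    average (the convention consistent with high methylation => late);
    ``"positive"`` uses the opposite indicator.
    """
    ok = windows["rt"].notna()
    if not ok.any():
        raise InsufficientDataError("no non-missing windows")
    lw = windows.loc[ok, "length_bp"].to_numpy(dtype=float)
    rt = windows.loc[ok, "rt"].to_numpy(dtype=float)
    rt_mean = float((lw * rt).sum() / lw.sum())
    late = rt < 0 if late_sign == "negative" else rt > 0
    frac_late = float((lw * late).sum() / lw.sum())
    return SampleRTSummary(sample_id=sample_id, rt_mean=rt_mean, frac_late=frac_late)


def gene_tss(manifest: pd.DataFrame) -> pd.DataFrame:
    """Most 5' promoter-probe position per gene (gene, chrom, pos)."""
    prom = manifest[manifest["region_class"].isin(PROMOTER_CLASSES)]
    pairs = prom.explode("genes").dropna(subset=["genes"])
    pairs = pairs[pairs["genes"] != ""]
    idx = pairs.groupby("genes")["pos"].idxmin()
    out = pairs.loc[idx, ["genes", "chrom", "pos"]].rename(columns={"genes": "gene"})
    return out.reset_index(drop=True)


def gene_rt_from_domains(
    domains: pd.DataFrame, manifest: pd.DataFrame, genes=None
) -> pd.Series:
    """RT of the domain containing each gene's most-5' promoter probe."""
    tss = gene_tss(manifest)
    if genes is not None:
        missing = [g for g in genes if g not in set(tss["gene"])]
        if missing:
            warnings.warn(f"genes without promoter coordinates excluded: {missing}")
        tss = tss[tss["gene"].isin(genes)]
    out = {}
    for row in tss.itertuples():
        dom = domains[
            (domains["chrom"] == row.chrom)
            & (domains["start"] <= row.pos)
            & (row.pos < domains["end"])
        ]
        out[row.gene] = float(dom["rt_domain"].iloc[0]) if len(dom) else np.nan
    return pd.Series(out, name="rt_domain").sort_index()


def compute_rt_assets(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    grid: WindowGrid,
    rt_cfg: RTConfig | None = None,
    genes=None,
):
    """Run the window/RT/domain chain for every sample.

    Returns (per-sample windows dict, per-sample domains dict, summaries
    DataFrame, gene x sample RT profile matrix).
    """
    rt_cfg = rt_cfg or RTConfig()
    windows_by_sample = {}
    domains_by_sample = {}
    summaries = []
    profiles = {}
    for sample in betas.sample_ids:
        win = bin_and_smooth(
            betas.beta[sample], manifest, grid, rt_cfg.smoothing_width
        )
        win = methylation_to_rt(win)
        dom = aggregate_domains(win, rt_cfg.domain_bp)
        summ = sample_summary(win, sample_id=sample, late_sign=rt_cfg.late_sign)
        windows_by_sample[sample] = win
        domains_by_sample[sample] = dom
        summaries.append(summ)
        profiles[sample] = gene_rt_from_domains(dom, manifest, genes=genes)
    summary_df = pd.DataFrame(
        [(s.sample_id, s.rt_mean, s.frac_late) for s in summaries],
        columns=["sample_id", "rt_mean", "frac_late"],
    ).set_index("sample_id")
    profile_df = pd.DataFrame(profiles)
    return windows_by_sample, domains_by_sample, summary_df, profile_df
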