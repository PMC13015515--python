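"""Synthetic cohort generator with planted structure.

Emulates the four inputs of the real pancreatic-cancer analysis — per-sample
promoter methylation files, an Illumina-450K-style probe manifest, a
gene x sample expression matrix, basal/classical subtype labels and
patient-level morphology embeddings — on a toy genome, with known ground
truth for every downstream stage:

* **Replication timing**: each toy chromosome carries one contiguous block of
  late-replicating windows (anchored at the chromosome start) covering
  ``late_fraction_planted`` of its windows; probes inside late windows draw
  systematically higher beta values, so the inverted-methylation RT proxy
  can recover the planted late fraction.
* **Gene programs**: the first two gene modules are the anticorrelated
  basal and classical expression programs.  Their shared activity is the
  subtype shift (``±subtype_effect_size/2`` on the unit latent scale of a
  background gene) plus a small subtype-independent activity noise, so the
  cohort-level within-module correlation is dominated by the subtype split —
  the regime in which single-sample network scores carry subtype signal.
  Remaining modules are subtype-free blocks at the same target correlation.
* **Morphology**: the first embedding dimension separates subtypes at
  ``embedding_effect_size``; all other dimensions are standard normal noise.

Expression is produced from a Gaussian copula over the block covariance and
exponentiated to positive values, resembling normalized expression while
approximately preserving the target Pearson structure.  Beta values are
clipped to [0.01, 0.99] before writing.  Generation is byte-deterministic
in the seed.  Methylation files alternate between two dialects (comma +
header, tab headerless) to exercise column auto-detection downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# latent-to-expression scale: X = 100 * exp(LATENT_SD * z); small enough that
# exponentiation barely attenuates Pearson correlations
LATENT_SD = 0.3

PROMOTER_CLASS_CYCLE = ("TSS200", "TSS1500", "5UTR", "First Exon")

# below this shift-driven variance the subtype split cannot dominate the
# program correlation; fall back to an ordinary correlated block plus shift
_MIN_SHIFT_VAR = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 120
    n_genes: int = 50
    n_modules: int = 3
    genes_per_module: int = 15
    within_module_corr: float = 0.8
    between_program_corr: float = -0.4
    basal_fraction: float = 0.6
    subtype_effect_size: float = 1.0
    probes_per_promoter: int = 3
    beta_noise_sd: float = 0.05
    late_fraction_planted: float = 0.3
    embedding_dim: int = 1300
    embedding_effect_size: float = 1.0
    seed: int = 1337
    # toy genome geometry
    n_chroms: int = 3
    chrom_bp: int = 6_000_000
    window_bp: int = 200_000
    # within-subtype sd of the program activity (unit latent scale)
    program_activity_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.basal_fraction < 1:
            raise ConfigurationError("basal_fraction must be in (0, 1)")
        nb = _n_basal(self.basal_fraction, self.n_samples)
        if nb < 2 or self.n_samples - nb < 2:
            raise ConfigurationError("need at least 2 samples per subtype")
        if not 0 <= self.within_module_corr <= 1:
            raise ConfigurationError("within_module_corr must be in [0, 1]")
        if not -1 <= self.between_program_corr <= 0:
            raise ConfigurationError("between_program_corr must be in [-1, 0]")
        if not 0 <= self.late_fraction_planted <= 1:
            raise ConfigurationError("late_fraction_planted must be in [0, 1]")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ConfigurationError("modules require more genes than n_genes")
        if self.n_modules < 1 or self.genes_per_module < 2:
            raise ConfigurationError("need >= 1 module of >= 2 genes")
        if self.chrom_bp // self.window_bp < 10:
            raise ConfigurationError("need >= 10 windows per chromosome")


def _n_basal(basal_fraction: float, n_samples: int) -> int:
    """Floor, then assign the fractional remainder to basal."""
    exact = basal_fraction * n_samples
    nb = math.floor(exact)
    if exact - nb > 1e-9:
        nb += 1
    return nb


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


@dataclass
class WindowGrid:
    """Uniform non-overlapping windows over a set of toy chromosomes."""

    windows: pd.DataFrame  # columns: chrom, start, end

    @classmethod
    def uniform(cls, chrom_sizes: dict[str, int], window_bp: int) -> "WindowGrid":
        rows = []
        for chrom, size in chrom_sizes.items():
            for start in range(0, size, window_bp):
                rows.append((chrom, start, min(start + window_bp, size)))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def n_windows(self, chrom: str) -> int:
        return int((self.windows["chrom"] == chrom).sum())


def default_genome(config: SyntheticConfig) -> WindowGrid:
    sizes = {f"chr{i + 1}": config.chrom_bp for i in range(config.n_chroms)}
    return WindowGrid.uniform(sizes, config.window_bp)


@dataclass
class PlantedRT:
    """Ground-truth early/late assignment per window."""

    windows: pd.DataFrame  # chrom, start, end, late (bool)

    @property
    def frac_late(self) -> float:
        return float(self.windows["late"].mean())


def plant_rt_structure(config: SyntheticConfig, genome: WindowGrid) -> PlantedRT:
    """Assign one contiguous late-replicating block per chromosome.

    The block is anchored at the chromosome start and covers
    ``round(late_fraction_planted * n_windows)`` windows, so the planted
    fraction is exact to within one window per chromosome.  Contiguity
    mimics the megabase scale of real replication domains and keeps the
    boundary distortion introduced by downstream smoothing to a couple of
    windows per chromosome.
    """
    win = genome.windows.copy()
    late = np.zeros(len(win), dtype=bool)
    for chrom, grp in win.groupby("chrom", sort=False):
        n_w = len(grp)
        if n_w < 10:
            raise ConfigurationError(f"{chrom}: need >= 10 windows, got {n_w}")
        k = int(round(config.late_fraction_planted * n_w))
        idx = grp.sort_values("start").index[:k]
        late[win.index.get_indexer(idx)] = True
    win["late"] = late
    return PlantedRT(win)


def simulate_labels(config: SyntheticConfig) -> pd.Series:
    """Subtype per sample; basal count = floor(fraction*n) + remainder."""
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    nb = _n_basal(config.basal_fraction, n)
    flags = np.array([True] * nb + [False] * (n - nb))
    _rng(config, 0).shuffle(flags)
    return pd.Series(
        np.where(flags, "basal", "classical"), index=sample_ids, name="subtype"
    )


def module_membership(config: SyntheticConfig) -> dict[str, list[str]]:
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    return {
        f"module_{m}": genes[
            m * config.genes_per_module : (m + 1) * config.genes_per_module
        ]
        for m in range(config.n_modules)
    }


def gene_positions(config: SyntheticConfig, genome: WindowGrid) -> pd.DataFrame:
    """Deterministic round-robin placement of gene TSSs along chromosomes."""
    chroms = sorted(genome.windows["chrom"].unique())
    n_chroms = len(chroms)
    counts = [
        len(range(c, config.n_genes, n_chroms)) for c in range(n_chroms)
    ]
    rows = []
    for g in range(config.n_genes):
        c = g % n_chroms
        ordinal = g // n_chroms
        chrom = chroms[c]
        chrom_len = int(genome.windows.loc[genome.windows["chrom"] == chrom, "end"].max())
        spacing = chrom_len // (counts[c] + 1)
        rows.append((f"G{g + 1:04d}", chrom, spacing * (ordinal + 1)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos"])


def build_probe_manifest(config: SyntheticConfig, genome: WindowGrid) -> pd.DataFrame:
    """Probe manifest: promoter probes per gene, body probes, window fillers.

    Every 20th promoter probe (5%) maps to exactly two genes (semicolon-
    joined), exercising the multi-gene probe expansion rule.  Filler probes
    (6 per window, no gene) guarantee every window has methylation signal.
    """
    pos_df = gene_positions(config, genome)
    rows = []
    counter = 0
    promoter_counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"cg{counter:08d}"

    for _, row in pos_df.iterrows():
        g_idx = int(row["gene"][1:]) - 1
        for j in range(config.probes_per_promoter):
            gene = row["gene"]
            if promoter_counter % 20 == 0 and config.n_genes > 1:
                partner = f"G{(g_idx + 1) % config.n_genes + 1:04d}"
                gene = f"{gene};{partner}"
            rows.append(
                (
                    next_id(),
                    gene,
                    PROMOTER_CLASS_CYCLE[j % len(PROMOTER_CLASS_CYCLE)],
                    row["chrom"],
                    int(row["pos"]) + 17 * j,
                )
            )
            promoter_counter += 1
        rows.append(
            (next_id(), row["gene"], "Body", row["chrom"], int(row["pos"]) + 2500)
        )
    for _, w in genome.windows.iterrows():
        span = int(w["end"]) - int(w["start"])
        for j in range(6):
            rows.append(
                (
                    next_id(),
                    "",
                    "Body",
                    w["chrom"],
                    int(w["start"]) + (j + 1) * span // 7,
                )
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "gene", "region_class", "chrom", "pos"]
    )


def simulate_expression(config: SyntheticConfig, labels: pd.Series) -> pd.DataFrame:
    """Gene x sample expression with planted block/program structure.

    Latent scale: background genes are unit-variance standard normals.  The
    basal program (first module) has shared activity ``+e/2`` in basal and
    ``-e/2`` in classical samples (e = subtype_effect_size), the classical
    program (second module) the mirror image; their residual activities are
    correlated at ``between_program_corr``.  Idiosyncratic gene noise is
    scaled so the cohort-level within-module Pearson correlation matches
    ``within_module_corr``.  When the shift-driven variance is too small to
    dominate (tiny effect sizes), programs degrade to ordinary correlated
    blocks carrying the residual shift.
    """
    rng = _rng(config, 1)
    n = config.n_samples
    p = config.n_genes
    w = config.within_module_corr
    e = config.subtype_effect_size
    rho_b = config.between_program_corr
    modules = module_membership(config)
    genes = [f"G{i + 1:04d}" for i in range(p)]
    basal = (labels.to_numpy() == "basal")
    bf = basal.mean()
    shift = np.where(basal, e / 2.0, -e / 2.0)

    # correlated program activity noise (always drawn, for determinism)
    z0 = rng.standard_normal(n)
    z1 = rho_b * z0 + np.sqrt(max(0.0, 1 - rho_b**2)) * rng.standard_normal(n)

    v_shift = e**2 * bf * (1 - bf)
    shift_dominated = v_shift >= _MIN_SHIFT_VAR and w > 0

    factors: dict[str, np.ndarray] = {}
    idio_sd: dict[str, float] = {}
    for m, (name, _) in enumerate(modules.items()):
        if m == 0 and config.n_modules >= 2:
            act = z0
        elif m == 1:
            act = z1
        else:
            act = rng.standard_normal(n)
        sign = {0: 1.0, 1: -1.0}.get(m, 0.0) if config.n_modules >= 2 else 0.0
        if sign != 0.0 and shift_dominated:
            spa = config.program_activity_sd
            vf = v_shift + spa**2
            factors[name] = sign * shift + spa * act
            idio_sd[name] = math.sqrt(vf * (1 - w) / w)
        elif w > 0:
            factors[name] = sign * shift + math.sqrt(w) * act
            idio_sd[name] = math.sqrt(1 - w)
        else:
            factors[name] = sign * shift
            idio_sd[name] = 1.0

    latent = np.empty((p, n))
    in_module = {}
    for name, members in modules.items():
        for g in members:
            in_module[g] = name
    for gi, g in enumerate(genes):
        noise = rng.standard_normal(n)
        if g in in_module:
            name = in_module[g]
            latent[gi] = factors[name] + idio_sd[name] * noise
        else:
            latent[gi] = noise

    expr = 100.0 * np.exp(LATENT_SD * latent)
    return pd.DataFrame(expr, index=genes, columns=list(labels.index))


def simulate_methylation(
    config: SyntheticConfig,
    manifest: pd.DataFrame,
    planted: PlantedRT,
) -> pd.DataFrame:
    """Probe x sample beta matrix: late windows run hot, plus probe noise."""
    rng = _rng(config, 2)
    win = planted.windows
    base = np.full(len(manifest), 0.3)
    for chrom, grp in win.groupby("chrom", sort=False):
        on_chrom = manifest["chrom"] == chrom
        starts = grp["start"].to_numpy()
        late = grp.sort_values("start")["late"].to_numpy()
        idx = np.searchsorted(np.sort(starts), manifest.loc[on_chrom, "pos"].to_numpy(), side="right") - 1
        idx = np.clip(idx, 0, len(late) - 1)
        base[on_chrom.to_numpy()] = np.where(late[idx], 0.7, 0.3)
    noise = rng.normal(0.0, config.beta_noise_sd, (len(manifest), config.n_samples))
    beta = np.clip(base[:, None] + noise, 0.01, 0.99)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    return pd.DataFrame(beta, index=manifest["probe_id"].to_numpy(), columns=sample_ids)


def simulate_embeddings(config: SyntheticConfig, labels: pd.Series) -> pd.DataFrame:
    """Sample x dimension embeddings; dimension 1 carries the subtype axis."""
    rng = _rng(config, 3)
    emb = rng.standard_normal((config.n_samples, config.embedding_dim))
    basal = (labels.to_numpy() == "basal")
    emb[:, 0] += np.where(basal, 1.0, -1.0) * config.embedding_effect_size / 2.0
    cols = [f"e{i + 1}" for i in range(config.embedding_dim)]
    return pd.DataFrame(emb, index=list(labels.index), columns=cols)


@dataclass
class CohortManifest:
    """Paths to every generated file plus the planted ground truth."""

    out_dir: str
    methylation_dir: str
    methylation_files: list = field(default_factory=list)
    manifest_path: str = ""
    expression_path: str = ""
    labels_path: str = ""
    embeddings_path: str = ""
    truth_path: str = ""
    truth: dict = field(default_factory=dict)


def generate_cohort(config: SyntheticConfig, out_dir) -> CohortManifest:
    """Write the full synthetic cohort to ``out_dir`` and return its manifest.

    Methylation files alternate between a comma-separated ``probe,beta``
    dialect with a header (even sample index) and a headerless tab-separated
    dialect (odd index).
    """
    out = Path(out_dir)
    meth_dir = out / "methylation"
    meth_dir.mkdir(parents=True, exist_ok=True)

    genome = default_genome(config)
    planted = plant_rt_structure(config, genome)
    manifest = build_probe_manifest(config, genome)
    labels = simulate_labels(config)
    expr = simulate_expression(config, labels)
    beta = simulate_methylation(config, manifest, planted)
    emb = simulate_embeddings(config, labels)

    meth_files = []
    for i, sample in enumerate(beta.columns):
        path = meth_dir / f"{sample}.txt"
        lines = []
        if i % 2 == 0:
            lines.append("probe,beta")
            for probe, val in beta[sample].items():
                lines.append(f"{probe},{val:.6f}")
        else:
            for probe, val in beta[sample].items():
                lines.append(f"{probe}\t{val:.6f}")
        path.write_text("\n".join(lines) + "\n")
        meth_files.append(str(path))

    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    expression_path = out / "expression.tsv"
    expr.to_csv(expression_path, sep="\t", float_format="%.6f", index_label="gene")
    labels_path = out / "labels.csv"
    labels.rename_axis("sample_id").to_frame().to_csv(labels_path)
    embeddings_path = out / "embeddings.tsv"
    emb.to_csv(embeddings_path, sep="\t", float_format="%.6f", index_label="sample_id")

    late_windows = [
        f"{r.chrom}:{int(r.start)}-{int(r.end)}"
        for r in planted.windows.itertuples()
        if r.late
    ]
    truth = {
        "config": asdict(config),
        "modules": module_membership(config),
        "subtypes": labels.to_dict(),
        "late_windows": late_windows,
        "planted_frac_late": planted.frac_late,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    return CohortManifest(
        out_dir=str(out),
        methylation_dir=str(meth_dir),
        methylation_files=meth_files,
        manifest_path=str(manifest_path),
        expression_path=str(expression_path),
        labels_path=str(labels_path),
        embeddings_path=str(embeddings_path),
        truth_path=str(truth_path),
        truth=truth,
    )
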