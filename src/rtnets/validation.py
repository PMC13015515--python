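"""Permutation nulls, bootstrap edge stability and mixing-grid sweeps.

The permutation null shuffles subtype labels (S times, seeded), recomputes
the tracked metrics under each shuffle and summarizes each metric as

    Z = (x_real - mu_shuffle) / sigma_shuffle
    p_emp = (1 + #{x_shuffle >= x_real}) / (1 + S)

so the smallest attainable empirical p is 1/(S+1).  Edge stability
resamples the cohort (without replacement, default 80%), rebuilds the
network on each subsample and compares top-K edge sets pairwise by Jaccard
similarity on unordered gene-pair identity.  The grid sweep enumerates the
full Cartesian product of (a, b, gamma) mixing weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .config import GridSpec


@dataclass
class NullResult:
    metric_name: str
    x_real: float
    shuffle_values: np.ndarray
    mu_shuffle: float
    sigma_shuffle: float
    z: float  # NaN when sigma is 0
    p_emp: float
    note: str = ""


def permutation_null(
    pipeline_fn: Callable[[pd.Series], dict],
    labels: pd.Series,
    n_shuffles: int = 100,
    seed: int = 1337,
) -> dict[str, NullResult]:
    """Label-permutation null for every metric ``pipeline_fn`` reports.

    ``pipeline_fn`` maps a label series (same index as ``labels``) to a
    dict of metric values; it is first evaluated on the real labels, then
    on ``n_shuffles`` seeded uniform permutations.  A failing shuffle is
    dropped (S decremented) with a warning.  Zero shuffle variance makes Z
    undefined (NaN, with a note); p_emp is always defined.
    """
    rng = np.random.default_rng(seed)
    real = pipeline_fn(labels)
    values = np.array(labels.to_numpy())
    shuffles: dict[str, list] = {k: [] for k in real}
    for s in range(n_shuffles):
        perm = pd.Series(rng.permutation(values), index=labels.index)
        try:
            out = pipeline_fn(perm)
        except Exception as exc:  # noqa: BLE001 - drop the shuffle, continue
            warnings.warn(f"shuffle {s} failed and was dropped: {exc}")
            continue
        for k in shuffles:
            shuffles[k].append(out[k])
    results = {}
    for k, vals in shuffles.items():
        arr = np.asarray(vals, dtype=float)
        s_eff = len(arr)
        mu = float(arr.mean()) if s_eff else np.nan
        sigma = float(arr.std(ddof=0)) if s_eff else np.nan
        x = float(real[k])
        if s_eff and sigma > 0:
            z, note = (x - mu) / sigma, ""
        else:
            z, note = np.nan, "zero shuffle variance; Z undefined"
        p_emp = (1 + int(np.sum(arr >= x))) / (1 + s_eff) if s_eff else np.nan
        results[k] = NullResult(
            metric_name=k,
            x_real=x,
            shuffle_values=arr,
            mu_shuffle=mu,
            sigma_shuffle=sigma,
            z=z,
            p_emp=p_emp,
            note=note,
        )
    return results


def jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass
class StabilityResult:
    n_boot: int
    frac: float
    top_k: int
    jaccard_values: np.ndarray  # all n_boot*(n_boot-1)/2 pairwise values
    pairs: list = field(default_factory=list)  # (boot_a, boot_b) indices

    @property
    def mean(self) -> float:
        return float(self.jaccard_values.mean())

    @property
    def sd(self) -> float:
        return float(self.jaccard_values.std(ddof=0))


def _top_edge_set(edges, top_k: int) -> frozenset:
    """Top-K unordered gene-pair keys from an edge table (or pair iterable)."""
    if isinstance(edges, pd.DataFrame):
        col = "w_int" if "w_int" in edges.columns else edges.columns[-1]
        ranked = edges.sort_values(
            [col, "gene_i", "gene_j"], ascending=[False, True, True],
            kind="mergesort",
        )
        if len(ranked) < top_k:
            warnings.warn(
                f"builder produced {len(ranked)} edges < top_k {top_k}; "
                "comparing over available edges"
            )
        pairs = ranked.head(top_k)[["gene_i", "gene_j"]].itertuples(index=False)
        return frozenset(tuple(sorted(p)) for p in pairs)
    return frozenset(tuple(sorted(p)) for p in edges)


def bootstrap_stability(
    network_builder: Callable[[pd.DataFrame], object],
    data: pd.DataFrame,
    n_boot: int = 50,
    frac: float = 0.8,
    top_k: int = 10_000,
    seed: int = 1337,
) -> StabilityResult:
    """Pairwise Jaccard of top-K edge sets over cohort subsamples.

    ``data`` holds samples in columns; each bootstrap draws
    ``ceil(frac * N)`` samples without replacement (seeded) and rebuilds
    the network with ``network_builder``.  Edge identity is the unordered
    gene pair; weights are ignored in the comparison.
    """
    rng = np.random.default_rng(seed)
    samples = np.array(data.columns)
    n_take = int(np.ceil(frac * len(samples)))
    edge_sets = []
    for _ in range(n_boot):
        chosen = rng.choice(samples, size=n_take, replace=False)
        edges = network_builder(data[list(chosen)])
        edge_sets.append(_top_edge_set(edges, top_k))
    vals = []
    pairs = []
    for i in range(n_boot):
        for j in range(i + 1, n_boot):
            vals.append(jaccard(edge_sets[i], edge_sets[j]))
            pairs.append((i, j))
    return StabilityResult(
        n_boot=n_boot,
        frac=frac,
        top_k=top_k,
        jaccard_values=np.asarray(vals),
        pairs=pairs,
    )


def grid_search(
    grid: GridSpec,
    evaluator: Callable[[float, float, float], dict],
) -> pd.DataFrame:
    """Full Cartesian sweep over (a, b, gamma) mixing weights.

    Each cell records whatever metrics ``evaluator`` returns; a failing
    cell is marked ``status="failed"`` and the sweep continues.  Row order
    is deterministic (a outermost, gamma innermost).
    """
    rows = []
    for a, b, g in grid.cells():
        row = {"a": a, "b": b, "gamma": g}
        try:
            row.update(evaluator(a, b, g))
            row["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - record and continue
            row["status"] = "failed"
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
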