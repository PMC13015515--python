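"""Single-sample network estimation by linear interpolation (LIONESS).

Given any deterministic aggregate edge function ``e(samples)``, the network
attributable to sample ``q`` out of ``N`` is recovered from the full-cohort
network and its leave-one-out counterpart:

    e(q) = N * e(all) - (N - 1) * e(-q)

The identity is exact for edge statistics that are sample means of
per-sample quantities and a first-order approximation otherwise (e.g. for
Pearson correlation).  The pair set is frozen from the global network
before individualization, so per-patient edge vectors are directly
comparable; leave-one-out recomputation is exact, not approximated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InsufficientDataError


@dataclass
class LionessSet:
    """Per-sample edge vectors sharing one edge index.

    ``e_q = N * e_all - (N - 1) * e_minus`` holds elementwise by
    construction.  Samples whose leave-one-out evaluation failed carry NaN
    vectors (tracked in ``failed``).
    """

    sample_ids: list
    edge_index: list
    e_all: np.ndarray
    e_minus: pd.DataFrame  # edges x samples
    e_q: pd.DataFrame  # edges x samples
    failed: list

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def lioness_networks(
    edge_fn: Callable[[pd.DataFrame], np.ndarray],
    data: pd.DataFrame,
    edge_index: list,
) -> LionessSet:
    """Individualize ``edge_fn`` over the samples (columns) of ``data``.

    ``edge_fn`` maps a sample-subset DataFrame (same rows, fewer columns) to
    an edge-weight vector aligned with ``edge_index``.  A failing
    leave-one-out evaluation (e.g. zero variance after removing a sample)
    flags that sample as missing; the run continues.
    """
    sample_ids = list(data.columns)
    n = len(sample_ids)
    if n < 3:
        raise InsufficientDataError("LIONESS requires N >= 3 samples")
    e_all = np.asarray(edge_fn(data), dtype=float)
    if e_all.shape != (len(edge_index),):
        raise ValueError("edge_fn output does not match edge_index length")

    minus = np.empty((len(edge_index), n))
    failed = []
    for k, q in enumerate(sample_ids):
        try:
            vec = np.asarray(edge_fn(data.drop(columns=[q])), dtype=float)
            if vec.shape != (len(edge_index),):
                raise ValueError("edge_fn output length changed on subset")
            minus[:, k] = vec
        except Exception as exc:  # noqa: BLE001 - degrade per-sample
            warnings.warn(f"edge_fn failed for leave-out of {q}: {exc}")
            minus[:, k] = np.nan
            failed.append(q)

    e_minus = pd.DataFrame(minus, columns=sample_ids)
    e_minus.index = pd.Index(range(len(edge_index)))
    e_q = n * e_all[:, None] - (n - 1) * e_minus
    return LionessSet(
        sample_ids=sample_ids,
        edge_index=list(edge_index),
        e_all=e_all,
        e_minus=e_minus,
        e_q=e_q,
        failed=failed,
    )
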