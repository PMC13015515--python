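"""Run configuration.

All tunable parameters of the pipeline live in small dataclasses that
serialize to and round-trip from a single YAML file.  Defaults follow the
parameterization used for the pancreatic-cancer cohort analysis: a 0.5
absolute correlation floor, 5000 global / 500 plot top-K edges, a minimum of
five non-missing samples per gene, seed 1337, an RNA/replication-timing mix
of (a, b, gamma) = (1.0, 0.5, 0.5), 100 label shuffles, 50 bootstrap
iterations at an 80% resample fraction with a 10000-edge stability top-K,
and grid ranges a: 0.5..1.5, b: 0..1, gamma: 0..1 in steps of 0.25.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError


@dataclass
class MixConfig:
    """Edge-weight mixing and selection parameters.

    ``w_int = alpha * w_rna + beta_mix * s_rt_signed + gamma * norm(w_rna)``
    with thresholding at ``tau`` followed by global top-K selection.
    """

    alpha: float = 1.0
    beta_mix: float = 0.5
    gamma: float = 0.5
    tau: float = 0.5
    top_k_global: int = 5000
    top_k_plot: int = 500
    min_samples: int = 5
    min_abs_corr: float = 0.5
    use_partial: bool = False
    seed: int = 1337

    def __post_init__(self) -> None:
        if self.top_k_plot > self.top_k_global:
            raise ConfigurationError(
                f"top_k_plot ({self.top_k_plot}) must not exceed "
                f"top_k_global ({self.top_k_global})"
            )
        if self.min_samples < 3:
            raise ConfigurationError("min_samples must be >= 3")


@dataclass
class GridSpec:
    """Inclusive (start, stop, step) sweep ranges for the mixing weights."""

    a_range: tuple = (0.5, 1.5, 0.25)
    b_range: tuple = (0.0, 1.0, 0.25)
    g_range: tuple = (0.0, 1.0, 0.25)

    def __post_init__(self) -> None:
        for name in ("a_range", "b_range", "g_range"):
            rng = tuple(float(x) for x in getattr(self, name))
            if len(rng) != 3 or rng[2] <= 0 or rng[1] < rng[0]:
                raise ConfigurationError(f"invalid grid range {name}={rng}")
            setattr(self, name, rng)

    @staticmethod
    def _values(rng: tuple) -> list[float]:
        start, stop, step = rng
        vals = np.arange(start, stop + step / 2.0, step)
        return [float(v) for v in np.round(vals, 10)]

    def cells(self) -> list[tuple[float, float, float]]:
        """Full Cartesian sweep, a outermost, deterministic order."""
        return [
            (a, b, g)
            for a in self._values(self.a_range)
            for b in self._values(self.b_range)
            for g in self._values(self.g_range)
        ]


@dataclass
class RTConfig:
    """Replication-timing proxy parameters.

    Uniform genomic windows of ``window_bp`` (L = 200 kb) are summarized by
    the median beta, smoothed by a centered rolling mean of odd width, then
    z-scored genome-wide and sign-inverted to give the RT proxy.  Domains
    are fixed spans of ``domain_bp``.  ``late_sign`` picks the lateness
    indicator convention: "negative" means a window is late when its RT
    proxy is below average (high methylation), "positive" the opposite.
    """

    window_bp: int = 200_000
    domain_bp: int = 300_000
    smoothing_width: int = 3
    late_sign: str = "negative"
    hypo_thresh: float = -1.0
    hyper_thresh: float = 1.0

    def __post_init__(self) -> None:
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ConfigurationError("smoothing_width must be odd and >= 1")
        if self.domain_bp < self.window_bp:
            raise ConfigurationError("domain_bp must be >= window_bp")
        if self.late_sign not in ("negative", "positive"):
            raise ConfigurationError("late_sign must be 'negative' or 'positive'")
        if not self.hypo_thresh < self.hyper_thresh:
            raise ConfigurationError("hypo_thresh must be < hyper_thresh")


@dataclass
class ValidationConfig:
    """Permutation-null and bootstrap-stability settings."""

    n_shuffles: int = 100
    n_boot: int = 50
    boot_frac: float = 0.8
    stability_top_k: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.boot_frac <= 1:
            raise ConfigurationError("boot_frac must be in (0, 1]")
        if self.n_shuffles < 1 or self.n_boot < 2:
            raise ConfigurationError("need n_shuffles >= 1 and n_boot >= 2")


@dataclass
class ModelConfig:
    """Subtype classifier and morphology-gate settings."""

    cv_folds: int = 5
    l2_c: float = 10.0
    morph_gate: str = "sigmoid_mult"
    positive_class: str = "basal"

    def __post_init__(self) -> None:
        if self.morph_gate not in ("sigmoid_mult", "off"):
            raise ConfigurationError("morph_gate must be 'sigmoid_mult' or 'off'")
        if self.positive_class not in ("basal", "classical"):
            raise ConfigurationError("positive_class must be basal or classical")


@dataclass
class RunConfig:
    """Top-level configuration: input paths plus all stage parameters."""

    methylation_dir: Optional[str] = None
    manifest: Optional[str] = None
    expression: Optional[str] = None
    labels: Optional[str] = None
    embeddings: Optional[str] = None
    out_dir: str = "rtnets_out"
    mix: MixConfig = field(default_factory=MixConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    rt: RTConfig = field(default_factory=RTConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 1337

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("mix", MixConfig),
            ("grid", GridSpec),
            ("validation", ValidationConfig),
            ("rt", RTConfig),
            ("model", ModelConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:  # unknown keys
            raise ConfigurationError(str(exc)) from exc
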