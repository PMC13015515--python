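"""Shared fixtures: one small synthetic cohort generated per session."""

import pytest

from rtnets.config import RunConfig
from rtnets.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_samples=40, embedding_dim=16, seed=1337)


@pytest.fixture(scope="session")
def small_cohort(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(small_config, out)


@pytest.fixture(scope="session")
def small_run_config(small_cohort, tmp_path_factory) -> RunConfig:
    return RunConfig(
        methylation_dir=small_cohort.methylation_dir,
        manifest=small_cohort.manifest_path,
        expression=small_cohort.expression_path,
        labels=small_cohort.labels_path,
        embeddings=small_cohort.embeddings_path,
        out_dir=str(tmp_path_factory.mktemp("run_out")),
    )
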