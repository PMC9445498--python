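"""Shared fixtures: synthetic catalogues and trained model grids.

The heavyweight benchmark registry (18 models at full planting strength) is
session-scoped so the training/evaluation/scanning tests share one fit.
"""

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from plantdti import (
    benchmark_config, positives_from_catalogue, read_interaction_catalogue,
    sample_catalogue, train_suite,
)
from plantdti.io_tables import write_interaction_catalogue

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """The reference benchmark catalogue, loaded back through the TSV reader."""
    config = benchmark_config(seed=1)
    catalogue = sample_catalogue(config)
    path = tmp_path_factory.mktemp("bench") / "catalogue.tsv"
    write_interaction_catalogue(path, catalogue.df)
    tfs, motifs, links, report = read_interaction_catalogue(path)
    positives = positives_from_catalogue(tfs, motifs, links)
    return SimpleNamespace(
        config=config, catalogue=catalogue, path=path,
        tfs=tfs, motifs=motifs, links=links, report=report, positives=positives,
    )


@pytest.fixture(scope="session")
def benchmark_registry(benchmark):
    """Full 18-model grid trained on the benchmark (both schemes, 9 lengths)."""
    return train_suite(benchmark.positives, seed=1)


@pytest.fixture(scope="session")
def mini_benchmark():
    """A small 2-length catalogue for cheap training tests."""
    config = benchmark_config(seed=3, tfs_per_type=10, motifs_per_type=10, lengths=(7, 9))
    catalogue = sample_catalogue(config)
    positives = catalogue.positives()
    return SimpleNamespace(config=config, catalogue=catalogue, positives=positives)


@pytest.fixture(scope="session")
def mini_registry(mini_benchmark):
    """4-model grid (lengths 7 and 9, both schemes) for scan tests."""
    return train_suite(mini_benchmark.positives, seed=3)
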