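"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from snmcpipe.config import PipelineConfig
from snmcpipe.genome import Genome, build_cytosine_catalog
from snmcpipe.pipeline import run_pipeline
from snmcpipe.synthio import (
    LibraryParams,
    default_genome_spec,
    default_methylome_model,
    simulate_genome,
    simulate_library,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def syn():
    """The standard synthetic study genome (two autosomes + lambda)."""
    return simulate_genome(default_genome_spec(seed=101))


@pytest.fixture(scope="session")
def truth(syn):
    """Methylome truth for 3 cells of each of the 3 default cell types."""
    return simulate_methylome(syn, default_methylome_model(), 3, seed=102)


@pytest.fixture(scope="session")
def clean_library(syn, truth):
    """One cell's error-free library under the default (clean) tail model."""
    params = LibraryParams(
        seq_error_rate=0.0, dimer_fraction=0.0, duplicate_rate=0.0,
        lambda_spike_fraction=0.0,
    )
    reads, tdf = simulate_library(syn, truth, "L23_000", params, 1200, seed=103)
    return params, reads, tdf


@pytest.fixture(scope="session")
def contaminated_library(syn, truth):
    """The paired dNTP-carryover simulation: four-letter Adaptase tails."""
    params = LibraryParams.contaminated(
        seq_error_rate=0.0, dimer_fraction=0.0, duplicate_rate=0.0,
        lambda_spike_fraction=0.0,
    )
    reads, tdf = simulate_library(syn, truth, "L23_000", params, 1200, seed=103)
    return params, reads, tdf


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """End-to-end pipeline on the bundled study configuration (30 cells;
    5 kb bins fit the desk-scale genome; k=3 as in the recovery examples)."""
    cfg = PipelineConfig.from_dict(
        {"seed": 7, "cluster": {"bin_size": 5000, "k": 3}}
    )
    return run_pipeline(cfg, tmp_path_factory.mktemp("demo"), until="cluster")


@pytest.fixture(scope="session")
def tiny_genome():
    """A handcrafted two-contig genome small enough for exhaustive-scan
    alignment oracles."""
    import numpy as np

    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = {
        "tinyA": "".join(rng.choice(bases, size=2000, p=[0.29, 0.21, 0.21, 0.29])),
        "tinyB": "".join(rng.choice(bases, size=1500, p=[0.29, 0.21, 0.21, 0.29])),
    }
    return Genome(seqs)


@pytest.fixture(scope="session")
def tiny_catalog(tiny_genome):
    return build_cytosine_catalog(tiny_genome)
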