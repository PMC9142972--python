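"""Shared fixtures: one small simulated study (fold-verified planted
hairpins, four libraries, degradome peaks) reused across test modules."""

import pytest

from mirslice import pipeline, simulate
from mirslice.fold import PairMaxEngine, ViennaEngine

SMALL = dict(
    n_transcripts=40,
    n_planted_mirnas=8,
    depth_per_library=5_000,
    degradome_depth=10_000,
    n_planted_targets=5,
    n_cat4_targets=1,
    mean_mirna_reads_per_library=60.0,   # expression scaled to the depth
    mean_decoy_reads_per_library=40.0,
    seed=7,
)


@pytest.fixture(scope="session")
def vienna():
    return ViennaEngine()


@pytest.fixture(scope="session")
def pairmax():
    return PairMaxEngine()


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def study(small_config):
    return simulate.simulate_study(small_config)


@pytest.fixture(scope="session")
def result(study):
    return pipeline.run_pipeline(study)
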