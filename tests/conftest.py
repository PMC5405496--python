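"""Shared fixtures: a small synthetic genome and simulated/mapped samples.

Everything is generated programmatically at test time from fixed seeds;
module- and session-scoped so the expensive objects are built once.
"""

import numpy as np
import pytest

from micmac.genome import GeneratorConfig, make_genome
from micmac.mapping import SeedIndex, map_readset
from micmac.readsim import ReadSimConfig, mixture_for_fraction, simulate_sample

SMALL_CONFIG = GeneratorConfig(total_length=120_000, n_contigs=2)


@pytest.fixture(scope="session")
def small_model():
    return make_genome(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_indices(small_model):
    return SeedIndex(small_model.contigs), SeedIndex(small_model.somatic_contigs)


@pytest.fixture(scope="session")
def mixed_sample(small_model):
    """f=0.69 mixture at 50x on the small genome."""
    cfg = ReadSimConfig(coverage=50.0, seed=21)
    return simulate_sample(small_model, mixture_for_fraction(0.69, 50.0, "mix69"), cfg)


@pytest.fixture(scope="session")
def mixed_alignments(small_model, small_indices, mixed_sample):
    gi, si = small_indices
    return map_readset(gi, mixed_sample), map_readset(si, mixed_sample)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
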