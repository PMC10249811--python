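"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from retroscout.synthetic import SimConfig, generate_genome


@pytest.fixture(scope="session")
def toy():
    """A small two-chromosome genome with four multi-exon genes."""
    cfg = SimConfig(seed=11, genome_length=60_000, n_chroms=2, n_genes=4)
    genome, genes = generate_genome(cfg, np.random.default_rng(11))
    return cfg, genome, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
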