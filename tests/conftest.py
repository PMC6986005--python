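"""Shared fixtures: one small synthetic world, generated once per session."""

from __future__ import annotations

import pytest

from plastokit.align import TargetIndex, spliced_map
from plastokit.synthetic import generate_genome, scaled_spec, simulate_isoseq

SCALED_SEED = 7


@pytest.fixture(scope="session")
def scaled_world():
    """1/20-scale plastome with genes, introns, editing sites and operons."""
    genome, annotation, truth = generate_genome(scaled_spec(20, seed=SCALED_SEED))
    return genome, annotation, truth


@pytest.fixture(scope="session")
def scaled_index(scaled_world):
    genome, _, _ = scaled_world
    return TargetIndex.build(genome, k=13)


@pytest.fixture(scope="session")
def mapped_scaled(scaled_world, scaled_index):
    """Alignments of a 60x Iso-Seq simulation at 1% error."""
    genome, annotation, truth = scaled_world
    reads = simulate_isoseq(genome, truth, depth=60, error_rate=0.01,
                            seed=SCALED_SEED + 100, intron_retention=0.2)
    alns = [a for a in (spliced_map(r, scaled_index) for r in reads)
            if a is not None]
    return alns, reads
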