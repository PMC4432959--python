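"""Shared fixtures: small seeded synthetic datasets reused across modules."""

import pytest

from reannot import SimConfig, generate_genome_annotation, spawn_isoforms


@pytest.fixture(scope="session")
def sim():
    """A 60-gene synthetic genome with canonical isoforms and truth."""
    cfg = SimConfig(seed=11, n_genes=60, n_scaffolds=2,
                    scaffold_len_range=(140_000, 160_000))
    genome, annotation, truth = generate_genome_annotation(cfg)
    return cfg, genome, annotation, truth


@pytest.fixture(scope="session")
def iso_sim(sim):
    """The same genome with alternative isoforms carrying known AS events."""
    cfg, genome, annotation, truth = sim
    iso_ann, as_truth = spawn_isoforms(annotation, cfg.isoform_event_mix,
                                       seed=21, genome=genome)
    return cfg, genome, iso_ann, truth, as_truth
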