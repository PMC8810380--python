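import numpy as np
import pytest

from mutbias.simulate import (
    MutationGeneratorConfig,
    SyntheticGenomeConfig,
    TrackGeneratorConfig,
    TrackSpec,
    generate_genome,
    generate_mutations,
    generate_tracks,
)


@pytest.fixture(scope="session")
def small_genome():
    """A 20-gene, ~100-kb synthetic genome shared across tests."""
    cfg = SyntheticGenomeConfig(n_genes=20, seed=11)
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def toy_genome():
    """A tiny 3-gene genome (~5 kb) for enumeration-style checks."""
    cfg = SyntheticGenomeConfig(
        n_genes=3,
        seed=5,
        intergenic_length_range=(300, 600),
        exon_count_range=(1, 3),
    )
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def tracked_genome(small_genome):
    """Genome + two tracks + mutations placed by a known linear rate."""
    seqs, ann = small_genome
    tcfg = TrackGeneratorConfig(
        tracks=[
            TrackSpec("h3k4me1", {"gene_body": 0.7, "intergenic": 0.2}),
            TrackSpec("atac", {"gene_body": 0.3, "intergenic": 0.5}),
        ],
        noise_sd=0.05,
    )
    tracks = generate_tracks(ann, tcfg, seed=12)
    mcfg = MutationGeneratorConfig(
        baseline_rate=1.0,
        coefficients={"h3k4me1": -0.8, "atac": 0.5},
        n_mutations=4000,
        n_lines=5,
    )
    muts = generate_mutations(ann, seqs, tracks, mcfg, seed=13)
    return seqs, ann, tracks, muts


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
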