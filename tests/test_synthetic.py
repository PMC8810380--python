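"""Synthetic-data generator: determinism, composition and rate targets."""

import numpy as np
import pytest

from mutbias.genome import KIND_CODES, kind_code_arrays, write_fasta, write_gff3
from mutbias.simulate import (
    MutationGeneratorConfig,
    SyntheticGenomeConfig,
    TrackGeneratorConfig,
    TrackSpec,
    generate_genome,
    generate_mutations,
    generate_tracks,
    simulate_region_table,
)


def test_no_genes_gives_pure_intergenic():
    seqs, ann = generate_genome(SyntheticGenomeConfig(n_genes=0, seed=1))
    assert ann.genes == []
    assert sum(len(s) for s in seqs.values()) > 0


def test_same_seed_byte_identical(tmp_path):
    for sub in ("a", "b"):
        seqs, ann = generate_genome(SyntheticGenomeConfig(n_genes=5, seed=42))
        write_fasta(seqs, str(tmp_path / f"{sub}.fa"))
        write_gff3(ann, seqs, str(tmp_path / f"{sub}.gff3"))
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


def test_cds_gc_matches_configuration():
    """Realized CDS GC over >=100 kb within 0.02 of the configured 0.6."""
    cfg = SyntheticGenomeConfig(
        n_genes=120,
        seed=7,
        exon_count_range=(2, 4),
        exon_length_range=(300, 500),
        intergenic_length_range=(200, 400),
        gc={"cds": 0.6, "intron": 0.32, "utr5": 0.38, "utr3": 0.33, "intergenic": 0.32},
    )
    seqs, ann = generate_genome(cfg)
    cds_seq = []
    for g in ann.genes:
        for f in g.features_of("cds"):
            cds_seq.append(seqs[g.chrom][f.start : f.end])
    cds = "".join(cds_seq)
    assert len(cds) >= 100_000
    gc = (cds.count("G") + cds.count("C")) / len(cds)
    assert 0.58 <= gc <= 0.62


def test_annotation_invariants_hold(small_genome):
    _, ann = small_genome
    ann.validate()  # raises on violation
    for g in ann.genes:
        cds = g.features_of("cds")
        total = sum(f.length for f in cds)
        assert total % 3 == 0


def test_noise_free_track_is_exact_step(small_genome):
    _, ann = small_genome
    cfg = TrackGeneratorConfig(
        tracks=[TrackSpec("t", {"gene_body": 0.8, "intergenic": 0.2})], noise_sd=0.0
    )
    (t,) = generate_tracks(ann, cfg, seed=0)
    codes = kind_code_arrays(ann)
    for chrom, v in t.values.items():
        body = codes[chrom] >= 3
        assert np.all(v[body] == 0.8)
        # flanks take the intergenic mean
        assert np.all(v[~body] == 0.2)


def test_gene_class_contrast_recovered():
    seqs, ann = generate_genome(SyntheticGenomeConfig(n_genes=200, seed=3))
    classes = {g.id: ("essential" if i % 2 == 0 else "other") for i, g in enumerate(ann.genes)}
    cfg = TrackGeneratorConfig(
        tracks=[
            TrackSpec(
                "h3k4me1",
                {"gene_body": 0.5, "intergenic": 0.1},
                class_means={"essential": 0.9},
            )
        ],
        gene_classes=classes,
        noise_sd=0.05,
    )
    (t,) = generate_tracks(ann, cfg, seed=4)
    means = {"essential": [], "other": []}
    for g in ann.genes:
        means[classes[g.id]].append(t.region_mean(g.chrom, g.start, g.end))
    assert abs(np.mean(means["essential"]) - 0.9) < 0.02
    assert abs(np.mean(means["other"]) - 0.5) < 0.02


def test_uncorrelated_tracks(small_genome):
    _, ann = small_genome
    cfg = TrackGeneratorConfig(
        tracks=[TrackSpec("a", {"gene_body": 0.5, "intergenic": 0.5}),
                TrackSpec("b", {"gene_body": 0.5, "intergenic": 0.5})],
        noise_sd=0.1,
        noise_correlation=0.0,
    )
    ta, tb = generate_tracks(ann, cfg, seed=5)
    va, vb = ta.values["chr1"], tb.values["chr1"]
    assert va.size >= 10_000
    assert abs(np.corrcoef(va, vb)[0, 1]) < 0.1


def test_zero_cds_multiplier_yields_no_cds_mutations(tracked_genome):
    seqs, ann, tracks, _ = tracked_genome
    cfg = MutationGeneratorConfig(
        baseline_rate=1.0, region_multiplier={"cds": 0.0}, n_mutations=2000
    )
    ms = generate_mutations(ann, seqs, tracks, cfg, seed=1)
    codes = kind_code_arrays(ann)
    hits = [codes[r.chrom][r.pos] for r in ms.df.itertuples()]
    assert KIND_CODES["cds"] not in hits


def test_uniform_rate_splits_binomially_between_chromosomes():
    seqs, ann = generate_genome(
        SyntheticGenomeConfig(n_genes=0, n_chromosomes=2, seed=9,
                              intergenic_length_range=(50_000, 50_000))
    )
    assert len(seqs["chr1"]) == len(seqs["chr2"])
    cfg = MutationGeneratorConfig(baseline_rate=1.0, n_mutations=10_000)
    ms = generate_mutations(ann, seqs, [], cfg, seed=2)
    n1 = (ms.df["chrom"] == "chr1").sum()
    n, p = 10_000, 0.5
    assert abs(n1 - n * p) < 3 * np.sqrt(n * p * (1 - p))


def test_gene_body_multiplier_halves_rate(tracked_genome):
    seqs, ann, tracks, _ = tracked_genome
    cfg = MutationGeneratorConfig(
        baseline_rate=1.0, region_multiplier={"gene_body": 0.5}, n_mutations=10_000
    )
    ms = generate_mutations(ann, seqs, tracks, cfg, seed=3)
    codes = kind_code_arrays(ann)
    body_len = sum(int((c >= 3).sum()) for c in codes.values())
    other_len = sum(c.size for c in codes.values()) - body_len
    in_body = sum(codes[r.chrom][r.pos] >= 3 for r in ms.df.itertuples())
    rate_ratio = (in_body / body_len) / ((len(ms) - in_body) / other_len)
    assert abs(rate_ratio - 0.5) < 0.05


def test_mutation_determinism(tracked_genome):
    seqs, ann, tracks, _ = tracked_genome
    cfg = MutationGeneratorConfig(n_mutations=500)
    a = generate_mutations(ann, seqs, tracks, cfg, seed=7)
    b = generate_mutations(ann, seqs, tracks, cfg, seed=7)
    assert a.df.equals(b.df)


def test_all_zero_rate_raises(tracked_genome):
    seqs, ann, tracks, _ = tracked_genome
    cfg = MutationGeneratorConfig(baseline_rate=0.0, n_mutations=10)
    with pytest.raises(ValueError, match="no mutable sites"):
        generate_mutations(ann, seqs, tracks, cfg, seed=0)


def test_snv_alts_follow_reference_conditioning(tracked_genome):
    seqs, ann, tracks, _ = tracked_genome
    cfg = MutationGeneratorConfig(n_mutations=2000, snv_fraction=1.0)
    ms = generate_mutations(ann, seqs, tracks, cfg, seed=8)
    assert (ms.df["ref"] != ms.df["alt"]).all()
    for r in ms.df.itertuples():
        assert seqs[r.chrom][r.pos] == r.ref


def test_region_table_counts_sum():
    df = simulate_region_table(
        500, {"x1": 2.0}, n_noise_predictors=2, n_mutations=5000, seed=0
    )
    assert df["snv_count"].sum() == 5000
    assert np.allclose(df["snv_rate"], df["snv_count"] / df["length"])
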