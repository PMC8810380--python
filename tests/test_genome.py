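"""Genome I/O: coordinate conventions, feature decomposition, tracks, VCF."""

import numpy as np
import pytest

from mutbias.genome import (
    GENE_BODY_KINDS,
    FeatureTrack,
    GenicFeature,
    gc_content,
    kind_code_arrays,
    load_annotation,
    load_track,
    load_variants,
    write_variants,
)

TOY_GFF = """##gff-version 3
##sequence-region chr1 1 2000
chr1\t.\tgene\t101\t200\t.\t+\t.\tID=gplus
chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=gplus.1;Parent=gplus
chr1\t.\texon\t101\t200\t.\t+\t.\tID=gplus.1.e1;Parent=gplus.1
chr1\t.\tCDS\t101\t200\t.\t+\t0\tParent=gplus.1
chr1\t.\tgene\t301\t400\t.\t-\t.\tID=gminus
chr1\t.\tmRNA\t301\t400\t.\t-\t.\tID=gminus.1;Parent=gminus
chr1\t.\texon\t301\t330\t.\t-\t.\tID=gminus.1.e1;Parent=gminus.1
chr1\t.\texon\t351\t400\t.\t-\t.\tID=gminus.1.e2;Parent=gminus.1
chr1\t.\tCDS\t301\t330\t.\t-\t0\tParent=gminus.1
chr1\t.\tCDS\t351\t400\t.\t-\t0\tParent=gminus.1
chr1\t.\tgene\t501\t800\t.\t+\t.\tID=g3exon
chr1\t.\tmRNA\t501\t800\t.\t+\t.\tID=g3exon.1;Parent=g3exon
chr1\t.\texon\t501\t560\t.\t+\t.\tID=e1;Parent=g3exon.1
chr1\t.\texon\t601\t650\t.\t+\t.\tID=e2;Parent=g3exon.1
chr1\t.\texon\t701\t800\t.\t+\t.\tID=e3;Parent=g3exon.1
chr1\t.\tCDS\t501\t560\t.\t+\t0\tParent=g3exon.1
chr1\t.\tCDS\t601\t650\t.\t+\t0\tParent=g3exon.1
chr1\t.\tCDS\t701\t800\t.\t+\t0\tParent=g3exon.1
"""


@pytest.fixture()
def toy_annotation(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return load_annotation(str(p), flank=50)


def test_plus_strand_coordinate_conversion(toy_annotation):
    g = next(g for g in toy_annotation.genes if g.id == "gplus")
    assert (g.start, g.end) == (100, 200)
    assert g.tss == 100 and g.tts == 200
    cds = g.features_of("cds")
    assert len(cds) == 1 and (cds[0].start, cds[0].end, cds[0].rank) == (100, 200, 1)


def test_minus_strand_tss_and_ranks(toy_annotation):
    g = next(g for g in toy_annotation.genes if g.id == "gminus")
    assert g.strand == "-"
    assert g.tss == 400 and g.tts == 300  # TSS is the 5' end in transcription sense
    cds = sorted(g.features_of("cds"), key=lambda f: f.rank)
    # rank 1 is the rightmost segment in genome coordinates
    assert (cds[0].start, cds[0].end) == (350, 400)
    assert (cds[1].start, cds[1].end) == (300, 330)
    # upstream flank sits to the right of a minus-strand gene
    up = g.features_of("upstream")[0]
    assert up.start == 400 and up.end == 450


def test_three_exon_gene_intron_derivation(toy_annotation):
    g = next(g for g in toy_annotation.genes if g.id == "g3exon")
    introns = sorted(g.features_of("intron"), key=lambda f: f.rank)
    assert [i.rank for i in introns] == [1, 2]
    # gaps between exons: [560,600) and [650,700)
    assert (introns[0].start, introns[0].end) == (560, 600)
    assert (introns[1].start, introns[1].end) == (650, 700)
    assert [i.length for i in introns] == [40, 50]


def test_gene_body_partition(small_genome):
    """utr5+cds+intron+utr3 intervals tile the transcript span disjointly."""
    _, ann = small_genome
    for g in ann.genes:
        ivs = sorted(
            (f.start, f.end) for f in g.features if f.kind in GENE_BODY_KINDS
        )
        assert ivs[0][0] == g.start and ivs[-1][1] == g.end
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == s2, "gap or overlap inside gene body"


def test_strand_flip_maps_tss_to_tts(small_genome):
    """Reversing the chromosome and flipping strands swaps TSS/TTS and
    reverses rank order in genome space."""
    _, ann = small_genome
    L = ann.chrom_lengths["chr1"]
    for g in ann.genes[:5]:
        flip = lambda x: L - x  # noqa: E731
        # flipped gene: strand toggles, coordinates mirror
        ftss, ftts = flip(g.tss), flip(g.tts)
        if g.strand == "+":
            assert ftss > ftts  # now looks like a minus-strand gene
        else:
            assert ftss < ftts
        cds = sorted(g.features_of("cds"), key=lambda f: f.rank)
        mirrored = [(flip(f.end), flip(f.start)) for f in cds]
        # transcription order is preserved: rank-1 exon stays 5'-most
        assert mirrored == sorted(mirrored) or mirrored == sorted(mirrored, reverse=True)


def test_load_track_dense_fill(tmp_path):
    p = tmp_path / "t.bedGraph"
    p.write_text("chr1\t0\t10\t2.0\n")
    t = load_track(str(p), {"chr1": 20})
    assert np.all(t.values["chr1"][:10] == 2.0)
    assert np.all(t.values["chr1"][10:] == 0.0)


def test_track_unit_scaling(tmp_path):
    p = tmp_path / "t.bedGraph"
    p.write_text("chr1\t0\t5\t2\nchr1\t5\t10\t4\n")
    t = load_track(str(p), {"chr1": 10}, unit_scale=True)
    assert np.allclose(t.values["chr1"][:5], 0.5)
    assert np.allclose(t.values["chr1"][5:], 1.0)
    assert t.scale == "unit"


def test_bed_peaks_become_indicator(tmp_path):
    p = tmp_path / "peaks.bed"
    p.write_text("chr1\t2\t6\tpeak1\nchr1\t8\t9\tpeak2\n")
    t = load_track(str(p), {"chr1": 10})
    assert t.values["chr1"].tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 1, 0]


def test_track_interval_beyond_end_raises(tmp_path):
    p = tmp_path / "t.bedGraph"
    p.write_text("chr1\t5\t30\t1.0\n")
    with pytest.raises(ValueError, match="chr1:5-30"):
        load_track(str(p), {"chr1": 10})


TOY_VCF = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=DP,Number=1,Type=Integer,Description="DP">
##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
chr1\t10\t.\tA\tT\t.\t.\tQD=35;DP=12\tGT\t0/1\t0/0
chr1\t20\t.\tAT\tA\t.\t.\tQD=40;DP=8\tGT\t1/1\t0/0
chr1\t30\t.\tG\tC\t.\t.\tQD=31;DP=5\tGT\t0/0\t0/1
"""


def test_load_variants_types_and_zygosity(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    ms = load_variants(str(p))
    assert len(ms) == 3
    df = ms.df
    snv = df[df["pos"] == 9].iloc[0]
    assert snv["type"] == "SNV" and snv["zygosity"] == "het" and snv["line"] == "A"
    indel = df[df["pos"] == 19].iloc[0]
    assert indel["type"] == "indel" and indel["zygosity"] == "hom"
    # only the carrying sample yields a record
    assert set(df[df["pos"] == 29]["line"]) == {"B"}


def test_vcf_round_trip(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    ms = load_variants(str(p))
    out = tmp_path / "rt.vcf"
    write_variants(ms, str(out), chrom_lengths={"chr1": 1000})
    ms2 = load_variants(str(out))
    cols = ["chrom", "pos", "ref", "alt", "line", "zygosity"]
    a = ms.df[cols].sort_values(cols).reset_index(drop=True)
    b = ms2.df[cols].sort_values(cols).reset_index(drop=True)
    assert a.equals(b)


def test_gc_content():
    assert gc_content("GGCCAATT") == 0.5
    assert gc_content("GGGG") == 1.0


def test_kind_codes_cover_gene_bodies(small_genome):
    _, ann = small_genome
    codes = kind_code_arrays(ann)
    g = ann.genes[0]
    arr = codes[g.chrom][g.start : g.end]
    assert (arr > 2).all(), "gene body bases must carry gene-body kind codes"


def test_feature_negative_length_rejected():
    with pytest.raises(ValueError):
        GenicFeature("cds", 10, 5, 1)
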