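"""Site-frequency statistics: Tajima's D, windowed scans, MAF, MK alpha,
loss-of-function classification, exon-rank summaries, residuals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutbias.genome import MutationSet, VariantRecord
from mutbias.popgen import (
    MKCounts,
    classify_lof,
    exon_rank_summary,
    minor_allele_frequency,
    mk_alpha,
    polymorphism_residuals,
    site_pi,
    tajima_constants,
    tajimas_d,
    windowed_scan,
)


def oracle_tajima_d(n, S, pi):
    """Independent constant-by-constant implementation (1989 formulas)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def brute_force_window(G):
    """O(n^2) pairwise-difference oracle on a diploid genotype matrix."""
    n_sites, n_samp = G.shape
    alleles = np.zeros((n_sites, 2 * n_samp), dtype=int)
    alleles[:, 0::2] = (G >= 1).astype(int)
    alleles[:, 1::2] = (G == 2).astype(int)
    n = 2 * n_samp
    pi = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi += (alleles[:, i] != alleles[:, j]).sum()
    pi /= n * (n - 1) / 2
    ac = G.sum(axis=1)
    S = int(((ac > 0) & (ac < n)).sum())
    return n, S, pi


def test_s_zero_undefined():
    assert np.isnan(tajimas_d(10, 0, 0.0))


def test_pi_equal_watterson_gives_zero():
    c = tajima_constants(10)
    S = 7
    assert tajimas_d(10, S, S / c["a1"]) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_against_formula_oracle():
    assert tajimas_d(10, 16, 3.2) == pytest.approx(oracle_tajima_d(10, 16, 3.2), abs=1e-12)


def test_small_n_raises():
    with pytest.raises(ValueError):
        tajimas_d(3, 5, 1.0)


def test_windowed_scan_matches_brute_force(rng):
    G = rng.integers(0, 3, size=(20, 25))
    pos = np.sort(rng.choice(5000, 20, replace=False))
    ws = windowed_scan(pos, G, 5000, window=5000)
    n, S, pi = brute_force_window(G)
    assert ws["S"].iloc[0] == S
    assert ws["pi"].iloc[0] == pytest.approx(pi, abs=1e-10)
    assert ws["D"].iloc[0] == pytest.approx(oracle_tajima_d(n, S, pi), abs=1e-10)


def test_window_without_variants_undefined():
    ws = windowed_scan(np.array([550]), np.array([[1] * 10]), 1000, window=100)
    assert ws.loc[0, "S"] == 0 and np.isnan(ws.loc[0, "D"])
    assert ws.loc[5, "S"] == 1


def test_scan_concatenation_invariance(rng):
    G = rng.integers(0, 3, size=(40, 10))
    pos = np.sort(rng.choice(2000, 40, replace=False))
    both = windowed_scan(pos, G, 2000, window=100)
    first = windowed_scan(pos[pos < 1000], G[pos < 1000], 1000, window=100)
    second = windowed_scan(pos[pos >= 1000] - 1000, G[pos >= 1000], 1000, window=100)
    merged = pd.concat([first, second], ignore_index=True)
    assert np.allclose(both["S"], merged["S"])
    assert np.allclose(both["D"], merged["D"], equal_nan=True)


def test_d_sign_for_singletons_and_intermediates():
    n_samp = 10  # 20 alleles
    # all singletons: one het in a different sample per site
    G = np.zeros((8, n_samp), dtype=int)
    for i in range(8):
        G[i, i % n_samp] = 1
    ws = windowed_scan(np.arange(8), G, 100, window=100)
    assert ws["D"].iloc[0] < 0
    # all intermediate frequency (half the samples hom-alt)
    G2 = np.zeros((8, n_samp), dtype=int)
    G2[:, : n_samp // 2] = 2
    ws2 = windowed_scan(np.arange(8), G2, 100, window=100)
    assert ws2["D"].iloc[0] > 0


def test_missing_genotypes_use_called_alleles():
    # genotypes 0/0,0/0,0/0,0/1 -> MAF 1/8
    assert minor_allele_frequency(1, 8) == pytest.approx(0.125)
    assert minor_allele_frequency(4, 8) == 0.5
    assert np.isnan(minor_allele_frequency(0, 0))
    # a missing genotype reduces the denominator
    G = np.array([[0, 0, 0, 1, -1]])
    ws = windowed_scan(np.array([5]), G, 10, window=10)
    assert ws["pi"].iloc[0] == pytest.approx(site_pi(np.array([1]), np.array([8]))[0])


@given(st.integers(0, 200), st.integers(1, 200))
@settings(max_examples=50, deadline=None)
def test_maf_never_exceeds_half(ac, an):
    if ac <= an:
        assert 0 <= minor_allele_frequency(ac, an) <= 0.5


def test_mk_alpha_values():
    assert mk_alpha(MKCounts(1, 1, 1, 1)) == pytest.approx(0.0)
    assert mk_alpha(MKCounts(2, 1, 1, 1)) == pytest.approx(-1.0)
    assert np.isnan(mk_alpha(MKCounts(1, 0, 1, 1)))  # Ps = 0
    assert np.isnan(mk_alpha(MKCounts(1, 1, 0, 1)))  # Dn = 0


def _single_cds_gene(small_genome):
    _, ann = small_genome
    return next(g for g in ann.genes if g.n_cds_exons >= 1)


def test_classify_lof_frameshift_threshold(small_genome):
    seqs, ann = small_genome
    g = next(g for g in ann.genes if g.strand == "+" and g.n_cds_exons == 1)
    cds = g.features_of("cds")[0]
    L = cds.length
    # frameshift at 95% of the CDS disrupts 5% -> not LoF
    pos_late = cds.start + int(0.95 * L)
    ref = seqs[g.chrom][pos_late : pos_late + 2]
    assert not classify_lof(pos_late, ref, ref[0], g, seqs)
    # at exactly 90% the remaining 10% meets the threshold (inclusive)
    pos_90 = cds.start + int(0.90 * L)
    ref = seqs[g.chrom][pos_90 : pos_90 + 2]
    assert classify_lof(pos_90, ref, ref[0], g, seqs)


def test_classify_lof_stop_gain(small_genome):
    seqs, ann = small_genome
    from mutbias.nullmodels import classify_effect, _revcomp

    found = False
    for g in ann.genes:
        if g.strand != "+" or g.n_cds_exons != 1:
            continue
        cds = g.features_of("cds")[0]
        cds_seq = seqs[g.chrom][cds.start : cds.end]
        for i in range(len(cds_seq) // 2, len(cds_seq) - 3):
            ref = cds_seq[i]
            for alt in "ACGT":
                if alt != ref and classify_effect(cds_seq, i, ref, alt) == "stop-gained":
                    assert classify_lof(cds.start + i, ref, alt, g, seqs)
                    found = True
                    break
            if found:
                break
        if found:
            break
    assert found, "no stop-gain candidate found in fixture"


def test_exon_rank_density_ratio(small_genome):
    """Doubled variant density in rank-1 exons shows up as ~2x cell rate."""
    seqs, ann = small_genome
    rng = np.random.default_rng(8)
    recs = []
    for g in ann.genes:
        for f in g.features_of("cds"):
            lam = 0.2 if f.rank == 1 else 0.1
            k = rng.poisson(lam * f.length)
            for p in rng.integers(f.start, f.end, size=k):
                recs.append(VariantRecord(g.chrom, int(p), "A", "T", "SNV", "L", "hom"))
    ms = MutationSet.from_records(recs)
    out = exon_rank_summary(ann, ms)
    multi = out[out["n_exons"] >= 2]
    r1 = multi[multi["rank"] == 1]["mean_rate"].mean()
    rother = multi[multi["rank"] > 1]["mean_rate"].mean()
    assert r1 / rother == pytest.approx(2.0, rel=0.25)


def test_exon_summary_invariant_to_gene_order(small_genome, tracked_genome):
    seqs, ann, _, muts = tracked_genome
    a = exon_rank_summary(ann, muts)
    shuffled = type(ann)(ann.chromosomes, list(reversed(ann.genes)))
    b = exon_rank_summary(shuffled, muts)
    pd.testing.assert_frame_equal(a, b)


def test_polymorphism_residuals_properties():
    rng = np.random.default_rng(9)
    idx = [f"g{i}" for i in range(200)]
    score = pd.Series(rng.random(200), index=idx)
    # perfectly linear -> all residuals zero
    poly = 2.0 * score + 1.0
    resid = polymorphism_residuals(poly, score)
    assert np.allclose(resid, 0.0)
    # noisy case: mean 0, sd 1 by construction
    poly2 = 2.0 * score + rng.standard_normal(200) * 0.3
    r2 = polymorphism_residuals(poly2, score)
    assert abs(r2.mean()) < 1e-10 and r2.std(ddof=1) == pytest.approx(1.0)
    # planted negative offset detected
    poly3 = poly2.copy()
    sub = idx[:50]
    poly3[sub] -= 1.0
    r3 = polymorphism_residuals(poly3, score)
    assert r3[sub].mean() < -0.5


def test_zero_variance_score_raises():
    s = pd.Series(1.0, index=list("abc"))
    with pytest.raises(ValueError, match="zero variance"):
        polymorphism_residuals(s, s)
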