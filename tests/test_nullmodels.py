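"""Random-mutation null models: coding effects, NS/S distributions,
expected synonymous counts, thinning and ratio tests."""

import numpy as np
import pytest

from mutbias.genome import KIND_CODES, kind_code_arrays
from mutbias.nullmodels import (
    CodingIndex,
    MutationSpectrum,
    classify_effect,
    coding_effect_fractions,
    enumerate_ns_ratio,
    expected_synonymous,
    ns_null_distribution,
    ratio_test,
    selection_thinning,
    simulate_random_mutations,
)


@pytest.mark.parametrize(
    "cds,pos,ref,alt,effect",
    [
        ("CTTAAA", 5, "A", "G", "synonymous"),  # AAA->AAG both Lys
        ("CTT", 2, "T", "C", "synonymous"),  # Leu->Leu
        ("TGGAAA", 2, "G", "A", "stop-gained"),  # TGG->TGA
        ("ATGAAA", 1, "T", "C", "non-synonymous"),  # Met->Thr
    ],
)
def test_classify_effect_genetic_code(cds, pos, ref, alt, effect):
    assert classify_effect(cds, pos, ref, alt) == effect


def test_classify_effect_ref_mismatch_raises():
    with pytest.raises(ValueError, match="ref mismatch"):
        classify_effect("ATG", 0, "C", "T")


def test_spectrum_strand_symmetry():
    spec = MutationSpectrum()
    # G alts are the complements of C alts with identical probabilities
    pc = spec.conditional_alt_probs("C")
    pg = spec.conditional_alt_probs("G")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for alt, p in pc.items():
        assert pg[comp[alt]] == pytest.approx(p)


def test_spectrum_validation():
    with pytest.raises(ValueError):
        MutationSpectrum({"C>T": 1.0})  # missing classes
    probs = {c: 1 / 6 for c in ("C>T", "C>A", "C>G", "T>A", "T>C", "T>G")}
    probs["C>T"] = 0.5  # no longer sums to 1
    with pytest.raises(ValueError):
        MutationSpectrum(probs)


def test_random_mutations_deterministic_and_binomial():
    rng_seqs = {"chr1": "ACGT" * 5000, "chr2": "ACGT" * 5000}
    spec = MutationSpectrum.uniform()
    a = simulate_random_mutations(rng_seqs, spec, 10_000, seed=1)
    b = simulate_random_mutations(rng_seqs, spec, 10_000, seed=1)
    assert a.df.equals(b.df)
    n1 = (a.df["chrom"] == "chr1").sum()
    assert abs(n1 - 5000) < 3 * np.sqrt(10_000 * 0.25)
    # alts never equal refs and follow conditioning
    assert (a.df["ref"] != a.df["alt"]).all()


def test_ns_null_requires_coding(toy_genome):
    seqs, ann = toy_genome
    empty_ann = type(ann)(ann.chromosomes, [])
    with pytest.raises(ValueError, match="no coding sites"):
        ns_null_distribution(seqs, empty_ann, MutationSpectrum(), reps=2)


def test_enumeration_matches_independent_translation_oracle(toy_genome):
    """Package enumeration vs a brute-force oracle that mutates the spliced
    CDS string directly and translates with Biopython."""
    from Bio.Seq import Seq

    seqs, ann = toy_genome
    spec = MutationSpectrum()
    idx = CodingIndex(seqs, ann)
    fracs = coding_effect_fractions(seqs, ann, spec, idx)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    totals = {"synonymous": 0.0, "non-synonymous": 0.0, "stop-gained": 0.0}
    for g in ann.genes:
        seq = seqs[g.chrom]
        parts = []
        for f in sorted(g.features_of("cds"), key=lambda x: x.rank):
            s = seq[f.start : f.end]
            parts.append(s if g.strand == "+" else "".join(comp[b] for b in reversed(s)))
        cds = "".join(parts)
        prot = str(Seq(cds).translate())
        for i, ref in enumerate(cds):
            cond = spec.conditional_alt_probs(ref)
            for alt, p in cond.items():
                mutated = cds[:i] + alt + cds[i + 1 :]
                prot2 = str(Seq(mutated).translate())
                ci = i // 3
                if prot2[ci] == prot[ci]:
                    totals["synonymous"] += p
                elif prot2[ci] == "*" and prot[ci] != "*":
                    totals["stop-gained"] += p
                else:
                    totals["non-synonymous"] += p
    z = sum(totals.values())
    for k in totals:
        assert fracs[k] == pytest.approx(totals[k] / z, abs=1e-12)


def test_null_distribution_converges_to_enumeration(toy_genome):
    seqs, ann = toy_genome
    spec = MutationSpectrum()
    idx = CodingIndex(seqs, ann)
    rho = enumerate_ns_ratio(seqs, ann, spec, idx)
    dist = ns_null_distribution(seqs, ann, spec, n_mut=5000, reps=300, seed=2, index=idx)
    se = dist.ratios.std(ddof=1) / np.sqrt(len(dist.ratios))
    assert abs(dist.mean - rho) < 3 * se
    assert dist.contains(rho)


def test_expected_synonymous_enumeration_scaling(toy_genome):
    seqs, ann = toy_genome
    spec = MutationSpectrum()
    idx = CodingIndex(seqs, ann)
    out = expected_synonymous(seqs, ann, spec, n=5000, reps=50, seed=3, index=idx)
    total = sum(len(s) for s in seqs.values())
    coding_fraction = idx.n_coding / total
    expected = coding_fraction * 5000 * out["synonymous_fraction"]
    assert out["mean"] == pytest.approx(expected, rel=0.05)


def test_thinning_limits(toy_genome):
    seqs, ann = toy_genome
    spec = MutationSpectrum.uniform()
    ms = simulate_random_mutations(seqs, spec, 2000, seed=4)
    assert len(selection_thinning(ms, ann, 0.0)) == len(ms)
    codes = kind_code_arrays(ann)
    kept = selection_thinning(ms, ann, 1.0, seed=5)
    hits = [codes[r.chrom][r.pos] for r in kept.df.itertuples()]
    assert KIND_CODES["cds"] not in hits
    # non-coding mutations untouched
    non_cds = sum(codes[r.chrom][r.pos] != KIND_CODES["cds"] for r in ms.df.itertuples())
    assert len(kept) == non_cds


def test_thinning_binomial(toy_genome):
    seqs, ann = toy_genome
    spec = MutationSpectrum.uniform()
    ms = simulate_random_mutations(seqs, spec, 10_000, seed=6)
    codes = kind_code_arrays(ann)
    n_cds = sum(codes[r.chrom][r.pos] == KIND_CODES["cds"] for r in ms.df.itertuples())
    kept = selection_thinning(ms, ann, 0.3, seed=7)
    n_cds_kept = sum(codes[r.chrom][r.pos] == KIND_CODES["cds"] for r in kept.df.itertuples())
    removed = n_cds - n_cds_kept
    assert abs(removed - 0.3 * n_cds) < 3 * np.sqrt(n_cds * 0.3 * 0.7)


def test_ratio_test_values():
    stat, p = ratio_test((10, 10), (20, 20))
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
    # hand-computed chi-squared: margins 40/40, E = 20 everywhere
    stat, p = ratio_test((30, 10), (10, 30))
    assert stat == pytest.approx(sum((o - 20) ** 2 / 20 for o in (30, 10, 10, 30)))
    with pytest.raises(ValueError, match="zero margin"):
        ratio_test((0, 0), (5, 5))
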