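"""Random-mutation null models over coding sequence.

Implements the machinery needed to ask "what would mutations look like with
no selection": a strand-symmetrized 6-class substitution spectrum, coding
effect classification against the standard genetic code, Monte Carlo
placement of random mutations over a genome, null distributions of the
non-synonymous:synonymous (NS/S) ratio, the expected synonymous mutation
count, 2x2 chi-squared ratio tests and an explicit "selection thinning"
positive control in which a fraction s of coding mutations is removed as
if dominant lethal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mutbias.genome import (
    KIND_CODES,
    GenomeAnnotation,
    MutationSet,
    kind_code_arrays,
)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six unordered, strand-symmetrized substitution classes
SPECTRUM_CLASSES = ("C>T", "C>A", "C>G", "T>A", "T>C", "T>G")

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@dataclass(frozen=True)
class MutationSpectrum:
    """Probabilities over the six strand-symmetrized substitution classes.

    Pyrimidine-centred notation: a G>A change on the forward strand is the
    C>T class on the complementary strand. Default is a transition-rich,
    C>T-dominant spectrum typical of plant germline SNVs (methylated-
    cytosine deamination inflates C>T).
    """

    probs: dict[str, float] = field(
        default_factory=lambda: {
            "C>T": 0.45,
            "C>A": 0.14,
            "C>G": 0.10,
            "T>A": 0.09,
            "T>C": 0.15,
            "T>G": 0.07,
        }
    )

    def __post_init__(self):
        if set(self.probs) != set(SPECTRUM_CLASSES):
            raise ValueError(f"spectrum must cover exactly {SPECTRUM_CLASSES}")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("spectrum probabilities must be non-negative")
        if abs(sum(self.probs.values()) - 1.0) > 1e-9:
            raise ValueError("spectrum probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "MutationSpectrum":
        return cls({c: 1 / 6 for c in SPECTRUM_CLASSES})

    @classmethod
    def from_mutations(cls, mutations: MutationSet) -> "MutationSpectrum":
        """Empirical spectrum of the SNVs in a mutation set."""
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        snvs = mutations.df[mutations.df["type"] == "SNV"]
        for r in snvs.itertuples():
            ref, alt = r.ref, r.alt
            if ref in "GA":
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            counts[f"{ref}>{alt}"] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no SNVs to build a spectrum from")
        return cls({c: n / total for c, n in counts.items()})

    def conditional_alt_probs(self, ref: str) -> dict[str, float]:
        """P(alt | ref base), renormalized over the three possible alts."""
        if ref in "CT":
            raw = {cls.split(">")[1]: p for cls, p in self.probs.items() if cls[0] == ref}
        elif ref in "GA":
            pyr = _COMPLEMENT[ref]
            raw = {
                _COMPLEMENT[cls.split(">")[1]]: p
                for cls, p in self.probs.items()
                if cls[0] == pyr
            }
        else:
            raise ValueError(f"reference base must be A/C/G/T, got {ref!r}")
        total = sum(raw.values())
        if total == 0:
            raise ValueError(f"spectrum has zero mass for reference base {ref}")
        return {a: p / total for a, p in raw.items()}

    def alt_prob_matrix(self) -> np.ndarray:
        """4x4 matrix M[ref, alt] of conditional alt probabilities."""
        m = np.zeros((4, 4))
        for ref in BASES:
            for alt, p in self.conditional_alt_probs(ref).items():
                m[_BASE_IDX[ref], _BASE_IDX[alt]] = p
        return m


# ---------------------------------------------------------------------------
# Coding-effect classification
# ---------------------------------------------------------------------------

def classify_effect(cds_seq: str, pos_in_cds: int, ref: str, alt: str) -> str:
    """Effect of a single-base change at ``pos_in_cds`` of a spliced CDS.

    ``cds_seq`` is the coding strand sequence (length divisible by 3).
    Returns one of ``synonymous`` / ``non-synonymous`` / ``stop-gained``;
    changes outside the CDS are the caller's business (``non-coding``).
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not 0 <= pos_in_cds < len(cds_seq):
        raise ValueError("position outside CDS")
    if cds_seq[pos_in_cds] != ref:
        raise ValueError(
            f"ref mismatch at CDS position {pos_in_cds}: sequence has "
            f"{cds_seq[pos_in_cds]}, variant says {ref}"
        )
    table = _codon_table()
    ci = pos_in_cds // 3
    codon = cds_seq[3 * ci : 3 * ci + 3]
    off = pos_in_cds % 3
    new_codon = codon[:off] + alt + codon[off + 1 :]
    aa_ref = table[codon]
    aa_alt = table[new_codon]
    if aa_alt == "*" and aa_ref != "*":
        return "stop-gained"
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


@dataclass
class CodingIndex:
    """Vectorized per-site coding-effect lookup for a genome.

    For every CDS base (in genome coordinates) and each of the three
    alternative bases, the coding effect is pre-classified once; random
    mutation replicates then reduce to array lookups. Effects are coded
    0 = non-coding, 1 = synonymous, 2 = non-synonymous, 3 = stop-gained.
    """

    sequences: dict[str, str]
    annotation: GenomeAnnotation
    # effect[chrom][pos, alt_idx] -> code (alt_idx indexes ACGT; ref col = 0)
    effect: dict[str, np.ndarray] = field(init=False)
    ref_codes: dict[str, np.ndarray] = field(init=False)
    coding_mask: dict[str, np.ndarray] = field(init=False)

    EFFECT_NAMES = ("non-coding", "synonymous", "non-synonymous", "stop-gained")

    def __post_init__(self):
        self.ref_codes = {
            c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in self.sequences.items()
        }
        lut = np.zeros(256, dtype=np.int8)
        for b, i in _BASE_IDX.items():
            lut[ord(b)] = i
        self.ref_codes = {c: lut[v] for c, v in self.ref_codes.items()}
        self.effect = {
            c: np.zeros((len(s), 4), dtype=np.int8) for c, s in self.sequences.items()
        }
        self.coding_mask = {
            c: np.zeros(len(s), dtype=bool) for c, s in self.sequences.items()
        }
        code = {"synonymous": 1, "non-synonymous": 2, "stop-gained": 3}
        for gene in self.annotation.genes:
            seq = self.sequences[gene.chrom]
            cds_feats = sorted(gene.features_of("cds"), key=lambda f: f.rank)
            if not cds_feats:
                continue
            parts = []
            coords = []  # genome coordinate of each CDS base, transcription order
            for f in cds_feats:
                if gene.strand == "+":
                    parts.append(seq[f.start : f.end])
                    coords.extend(range(f.start, f.end))
                else:
                    parts.append(_revcomp(seq[f.start : f.end]))
                    coords.extend(range(f.end - 1, f.start - 1, -1))
            cds_seq = "".join(parts)
            if len(cds_seq) % 3 != 0:
                warnings.warn(f"gene {gene.id}: CDS length not divisible by 3; skipped")
                continue
            eff = self.effect[gene.chrom]
            mask = self.coding_mask[gene.chrom]
            for i, gpos in enumerate(coords):
                mask[gpos] = True
                ref_cds = cds_seq[i]
                for alt_cds in BASES:
                    if alt_cds == ref_cds:
                        continue
                    e = classify_effect(cds_seq, i, ref_cds, alt_cds)
                    # convert the coding-strand alt back to the forward strand
                    alt_fwd = alt_cds if gene.strand == "+" else _COMPLEMENT[alt_cds]
                    eff[gpos, _BASE_IDX[alt_fwd]] = max(
                        eff[gpos, _BASE_IDX[alt_fwd]], code[e]
                    )

    @property
    def n_coding(self) -> int:
        return int(sum(m.sum() for m in self.coding_mask.values()))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Random mutation simulation
# ---------------------------------------------------------------------------

def _concat_layout(sequences: dict[str, str]):
    chroms = sorted(sequences)
    lengths = np.array([len(sequences[c]) for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return chroms, lengths, offsets


def simulate_random_mutations(
    sequences: dict[str, str],
    spectrum: MutationSpectrum,
    n: int,
    seed: int | np.random.Generator = 0,
    mask: dict[str, np.ndarray] | None = None,
) -> MutationSet:
    """Place ``n`` SNVs uniformly over the genome (optionally over a
    callability ``mask``), drawing alt alleles from the spectrum conditioned
    on the reference base."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms, lengths, offsets = _concat_layout(sequences)
    total = int(offsets[-1])
    if mask is None:
        flat = rng.integers(0, total, size=n)
    else:
        allowed = np.concatenate([np.flatnonzero(mask[c]) + offsets[i] for i, c in enumerate(chroms)])
        if allowed.size == 0:
            raise ValueError("mask allows no sites")
        flat = rng.choice(allowed, size=n)
    flat = np.sort(flat)
    ci = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[ci]
    m = spectrum.alt_prob_matrix()
    rows = []
    u = rng.random(n)
    for k in range(n):
        chrom = chroms[ci[k]]
        p = int(pos[k])
        ref = sequences[chrom][p]
        probs = m[_BASE_IDX[ref]]
        alt = BASES[int(np.searchsorted(np.cumsum(probs), u[k]))]
        rows.append((chrom, p, ref, alt, "SNV", "sim", "hom", np.nan, np.nan, None))
    return MutationSet(pd.DataFrame(rows, columns=list(MutationSet.empty().df.columns)))


def _sample_effects(
    index: CodingIndex,
    spectrum: MutationSpectrum,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Effect codes of ``n`` uniformly placed random SNVs (vectorized)."""
    chroms, lengths, offsets = _concat_layout(index.sequences)
    flat = rng.integers(0, int(offsets[-1]), size=n)
    ci = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[ci]
    m = spectrum.alt_prob_matrix()
    cum = np.cumsum(m, axis=1)
    effects = np.zeros(n, dtype=np.int8)
    u = rng.random(n)
    for i, c in enumerate(chroms):
        sel = ci == i
        if not sel.any():
            continue
        p = pos[sel]
        refs = index.ref_codes[c][p]
        alts = (cum[refs] < u[sel][:, None]).sum(axis=1)
        effects[sel] = index.effect[c][p, alts]
    return effects


@dataclass
class NullRatioDistribution:
    """Replicate NS/S ratios from a random-mutation null."""

    ratios: np.ndarray
    n_mut: int
    n_resampled: int = 0

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.quantile(self.ratios, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def contains(self, observed: float, level: float = 0.95) -> bool:
        lo, hi = self.interval(level)
        return lo <= observed <= hi


def ns_null_distribution(
    sequences: dict[str, str],
    annotation: GenomeAnnotation,
    spectrum: MutationSpectrum,
    n_mut: int = 10_000,
    reps: int = 10_000,
    seed: int = 0,
    index: CodingIndex | None = None,
) -> NullRatioDistribution:
    """Null distribution of the NS/S ratio under uniform random mutation.

    Per replicate, ``n_mut`` SNVs are placed uniformly, coding hits are
    classified by codon, and the (non-synonymous + stop-gained) : synonymous
    ratio is recorded. Replicates with zero synonymous hits are resampled
    (count reported).
    """
    if index is None:
        index = CodingIndex(sequences, annotation)
    if index.n_coding == 0:
        raise ValueError("no coding sites in genome")
    rng = np.random.default_rng(seed)
    ratios = np.empty(reps)
    n_resampled = 0
    i = 0
    while i < reps:
        eff = _sample_effects(index, spectrum, n_mut, rng)
        s = int((eff == 1).sum())
        ns = int((eff >= 2).sum())
        if s == 0:
            n_resampled += 1
            if n_resampled > 100 * reps:
                raise RuntimeError("synonymous hits essentially impossible")
            continue
        ratios[i] = ns / s
        i += 1
    if n_resampled:
        warnings.warn(f"{n_resampled} replicates with zero synonymous hits resampled")
    return NullRatioDistribution(ratios, n_mut, n_resampled)


def enumerate_ns_ratio(
    sequences: dict[str, str],
    annotation: GenomeAnnotation,
    spectrum: MutationSpectrum,
    index: CodingIndex | None = None,
) -> float:
    """Exact expected NS/S ratio by enumeration over every CDS site x alt,
    weighted by the spectrum. This is the reps -> infinity limit of
    :func:`ns_null_distribution` (ratio of expectations)."""
    fracs = coding_effect_fractions(sequences, annotation, spectrum, index)
    if fracs["synonymous"] == 0:
        raise ValueError("no synonymous changes possible")
    return (fracs["non-synonymous"] + fracs["stop-gained"]) / fracs["synonymous"]


def coding_effect_fractions(
    sequences: dict[str, str],
    annotation: GenomeAnnotation,
    spectrum: MutationSpectrum,
    index: CodingIndex | None = None,
) -> dict[str, float]:
    """P(effect | mutation hits a coding site) by exhaustive enumeration."""
    if index is None:
        index = CodingIndex(sequences, annotation)
    if index.n_coding == 0:
        raise ValueError("no coding sites in genome")
    m = spectrum.alt_prob_matrix()
    totals = np.zeros(4)
    for c in index.coding_mask:
        pos = np.flatnonzero(index.coding_mask[c])
        if pos.size == 0:
            continue
        refs = index.ref_codes[c][pos]
        eff = index.effect[c][pos]  # (n, 4)
        w = m[refs]  # (n, 4) P(alt | ref)
        for code in range(1, 4):
            totals[code] += float((w * (eff == code)).sum())
    total = totals[1:].sum()
    return {
        "synonymous": totals[1] / total,
        "non-synonymous": totals[2] / total,
        "stop-gained": totals[3] / total,
    }


def expected_synonymous(
    sequences: dict[str, str],
    annotation: GenomeAnnotation,
    spectrum: MutationSpectrum,
    n: int = 6182,
    reps: int = 100,
    seed: int = 0,
    index: CodingIndex | None = None,
) -> dict[str, float]:
    """Expected synonymous mutation count under uniform random mutation.

    Per replicate, ``n`` positions are placed uniformly; the coding hits are
    multiplied by the enumeration-exact synonymous fraction. Returns the
    replicate mean and a +/-2 s.e. interval, plus the fraction used.
    """
    if index is None:
        index = CodingIndex(sequences, annotation)
    frac = coding_effect_fractions(sequences, annotation, spectrum, index)["synonymous"]
    rng = np.random.default_rng(seed)
    chroms, lengths, offsets = _concat_layout(sequences)
    coding = np.concatenate([index.coding_mask[c] for c in chroms])
    vals = np.empty(reps)
    for r in range(reps):
        flat = rng.integers(0, int(offsets[-1]), size=n)
        vals[r] = coding[flat].sum() * frac
    se = vals.std(ddof=1) / np.sqrt(reps)
    return {
        "mean": float(vals.mean()),
        "lo": float(vals.mean() - 2 * se),
        "hi": float(vals.mean() + 2 * se),
        "synonymous_fraction": float(frac),
    }


# ---------------------------------------------------------------------------
# Selection thinning and ratio tests
# ---------------------------------------------------------------------------

def selection_thinning(
    mutations: MutationSet,
    annotation: GenomeAnnotation,
    s: float,
    seed: int = 0,
    coding_kinds: tuple[str, ...] = ("cds",),
) -> MutationSet:
    """Remove each coding-region mutation independently with probability
    ``s`` (dominant-lethal model); non-coding mutations are untouched."""
    if not 0 <= s <= 1:
        raise ValueError("s must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = kind_code_arrays(annotation)
    wanted = {KIND_CODES[k] for k in coding_kinds}
    df = mutations.df
    in_coding = np.array(
        [codes[r.chrom][r.pos] in wanted for r in df.itertuples()], dtype=bool
    )
    removed = in_coding & (rng.random(len(df)) < s)
    return mutations.subset(~removed)


def ratio_test(
    observed: tuple[int, int], reference: tuple[int, int]
) -> tuple[float, float]:
    """2x2 chi-squared test (df=1, no continuity correction) comparing two
    (NS, S) count pairs. Returns (statistic, p-value)."""
    table = np.array([observed, reference], dtype=float)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
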