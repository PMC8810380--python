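"""Site-frequency statistics around gene bodies.

Tajima's D from (n, S, pi), windowed genome scans from genotype matrices
(vcftools-style: per-site sample size is the number of called alleles),
minor allele frequencies, the McDonald-Kreitman alpha statistic,
loss-of-function classification and polymorphism-vs-predicted-rate
scaled residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mutbias.genome import GeneModel, GenomeAnnotation, MutationSet


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D as functions of sample size n
    (number of sequences)."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, pi: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences; NaN when S == 0 (undefined)."""
    if S < 0 or pi < 0:
        raise ValueError("S and pi must be non-negative")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    return float((pi - S / c["a1"]) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1)))


# ---------------------------------------------------------------------------
# Genotype matrices and windowed scans
# ---------------------------------------------------------------------------

def site_allele_counts(genotypes: np.ndarray, ploidy: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, called alleles) per site.

    ``genotypes`` is (n_sites, n_samples) with diploid dosage codes 0/1/2
    (-1 = missing), or 0/1 for haploid data (``ploidy=1``).
    """
    g = np.asarray(genotypes)
    called = (g >= 0).sum(axis=1) * ploidy
    ac = np.where(g >= 0, g, 0).sum(axis=1)
    return ac.astype(np.int64), called.astype(np.int64)


def site_pi(ac: np.ndarray, an: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2k(n-k)/(n(n-1)) from allele counts."""
    ac = np.asarray(ac, float)
    an = np.asarray(an, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * ac * (an - ac) / (an * (an - 1.0))
    return np.where(an > 1, pi, 0.0)


def windowed_scan(
    positions: np.ndarray,
    genotypes: np.ndarray,
    chrom_length: int,
    window: int = 100,
    chrom: str = "chr1",
    ploidy: int = 2,
) -> pd.DataFrame:
    """Per-window S, pi and Tajima's D tiling ``[0, chrom_length)``.

    pi uses per-site called-allele counts; the D constants use the mean
    called-allele count over the window's segregating sites (rounded),
    so with complete data they equal the common sample size. Windows with
    S = 0 get D = NaN.
    """
    positions = np.asarray(positions, dtype=np.int64)
    ac, an = site_allele_counts(genotypes, ploidy=ploidy)
    return windowed_scan_from_counts(positions, ac, an, chrom_length, window, chrom)


def windowed_scan_from_counts(
    positions: np.ndarray,
    ac: np.ndarray,
    an: np.ndarray,
    chrom_length: int,
    window: int = 100,
    chrom: str = "chr1",
) -> pd.DataFrame:
    order = np.argsort(positions, kind="stable")
    positions, ac, an = positions[order], np.asarray(ac)[order], np.asarray(an)[order]
    seg = (ac > 0) & (ac < an)
    pis = site_pi(ac, an)
    n_windows = int(np.ceil(chrom_length / window)) if chrom_length else 0
    starts = np.arange(n_windows) * window
    ends = np.minimum(starts + window, chrom_length)
    win_idx = positions // window
    S = np.zeros(n_windows, dtype=np.int64)
    pi_sum = np.zeros(n_windows)
    n_sum = np.zeros(n_windows)
    np.add.at(S, win_idx[seg], 1)
    np.add.at(pi_sum, win_idx[seg], pis[seg])
    np.add.at(n_sum, win_idx[seg], an[seg])
    D = np.full(n_windows, np.nan)
    nz = S > 0
    for w in np.flatnonzero(nz):
        n_eff = int(round(n_sum[w] / S[w]))
        if n_eff >= 4:
            D[w] = tajimas_d(n_eff, int(S[w]), float(pi_sum[w]))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n": np.where(S > 0, np.round(n_sum / np.maximum(S, 1)), np.nan),
            "S": S,
            "pi": pi_sum,
            "D": D,
        }
    )


def scan_vcf(
    path: str, chrom_lengths: dict[str, int], window: int = 100
) -> pd.DataFrame:
    """Windowed scan of a (possibly multi-chromosome) VCF of diploid GTs."""
    from cyvcf2 import VCF

    per_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_lengths}
    vcf = VCF(path)
    for v in vcf:
        if v.CHROM not in per_chrom:
            raise ValueError(f"chromosome {v.CHROM} not in chrom_lengths")
        gts = np.array([[g[0], g[1]] for g in v.genotypes])
        called = int((gts >= 0).sum())
        alt = int(((gts > 0) & (gts >= 0)).sum())
        per_chrom[v.CHROM].append((v.POS - 1, alt, called))
    frames = []
    for chrom, rows in per_chrom.items():
        if rows:
            pos, ac, an = map(np.array, zip(*rows))
        else:
            pos = ac = an = np.array([], dtype=np.int64)
        frames.append(
            windowed_scan_from_counts(pos, ac, an, chrom_lengths[chrom], window, chrom)
        )
    return pd.concat(frames, ignore_index=True)


def minor_allele_frequency(ac: int, an: int) -> float:
    """min(p, 1-p) over called alleles; NaN when no alleles are called."""
    if an <= 0:
        return float("nan")
    p = ac / an
    return float(min(p, 1 - p))


# ---------------------------------------------------------------------------
# McDonald-Kreitman alpha
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MKCounts:
    """Polymorphism (Pn, Ps) and divergence (Dn, Ds) counts for one gene."""

    pn: int
    ps: int
    dn: int
    ds: int

    def __post_init__(self):
        if min(self.pn, self.ps, self.dn, self.ds) < 0:
            raise ValueError("MK counts must be non-negative")


def mk_alpha(counts: MKCounts) -> float:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); NaN when Dn or Ps is zero."""
    if counts.dn == 0 or counts.ps == 0:
        return float("nan")
    return 1.0 - (counts.ds * counts.pn) / (counts.dn * counts.ps)


# ---------------------------------------------------------------------------
# Loss of function
# ---------------------------------------------------------------------------

def classify_lof(
    chrom_pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    sequences: dict[str, str],
    min_disrupted_fraction: float = 0.10,
) -> bool:
    """True iff the variant is a premature stop or a frameshift disrupting
    at least ``min_disrupted_fraction`` of the coding region.

    The disrupted fraction of a frameshift is the fraction of CDS bases at
    or downstream (in transcription order) of the lesion.
    """
    from mutbias.nullmodels import _revcomp, classify_effect

    cds_feats = sorted(gene.features_of("cds"), key=lambda f: f.rank)
    if not cds_feats:
        return False
    seq = sequences[gene.chrom]
    coords: list[int] = []
    parts = []
    for f in cds_feats:
        if gene.strand == "+":
            parts.append(seq[f.start : f.end])
            coords.extend(range(f.start, f.end))
        else:
            parts.append(_revcomp(seq[f.start : f.end]))
            coords.extend(range(f.end - 1, f.start - 1, -1))
    cds_seq = "".join(parts)
    try:
        cds_idx = coords.index(chrom_pos)
    except ValueError:
        return False  # outside CDS
    if len(ref) == 1 and len(alt) == 1:
        ref_cds = ref if gene.strand == "+" else _revcomp(ref)
        alt_cds = alt if gene.strand == "+" else _revcomp(alt)
        if len(cds_seq) % 3:
            return False
        return classify_effect(cds_seq, cds_idx, ref_cds, alt_cds) == "stop-gained"
    shift = abs(len(ref) - len(alt)) % 3
    if shift == 0:
        return False  # in-frame indel
    disrupted = 1.0 - cds_idx / len(cds_seq)
    return disrupted >= min_disrupted_fraction


# ---------------------------------------------------------------------------
# Exon-rank summaries
# ---------------------------------------------------------------------------

def exon_rank_summary(
    annotation: GenomeAnnotation,
    variants: MutationSet,
    site_counts: pd.DataFrame | None = None,
    max_exons: int | None = None,
) -> pd.DataFrame:
    """Per-(total exon count, exon rank) mean per-bp variant rate, and mean
    Tajima's D when per-site allele counts are supplied.

    ``site_counts``: optional frame with columns chrom, pos, ac, an for
    polymorphic sites; per-exon D is computed from the sites inside each
    exon and averaged (exons with S = 0 are skipped).
    """
    pos_by_chrom = {
        c: np.sort(g["pos"].to_numpy(np.int64)) for c, g in variants.df.groupby("chrom")
    }
    sites = None
    if site_counts is not None:
        sites = {
            c: (g["pos"].to_numpy(np.int64), g["ac"].to_numpy(np.int64), g["an"].to_numpy(np.int64))
            for c, g in site_counts.sort_values("pos").groupby("chrom")
        }
    rows = []
    for g in annotation.genes:
        cds = sorted(g.features_of("cds"), key=lambda f: f.rank)
        k = len(cds)
        if k == 0 or (max_exons is not None and k > max_exons):
            continue
        for f in cds:
            pos = pos_by_chrom.get(g.chrom)
            count = 0
            if pos is not None:
                count = int(np.searchsorted(pos, f.end) - np.searchsorted(pos, f.start))
            d_val = np.nan
            if sites is not None and g.chrom in sites:
                sp, sac, san = sites[g.chrom]
                lo, hi = np.searchsorted(sp, [f.start, f.end])
                if hi > lo:
                    seg = (sac[lo:hi] > 0) & (sac[lo:hi] < san[lo:hi])
                    S = int(seg.sum())
                    if S > 0:
                        pi = float(site_pi(sac[lo:hi], san[lo:hi])[seg].sum())
                        n_eff = int(round(san[lo:hi][seg].mean()))
                        if n_eff >= 4:
                            d_val = tajimas_d(n_eff, S, pi)
            rows.append((k, f.rank, f.length, count, count / f.length, d_val))
    df = pd.DataFrame(
        rows, columns=["n_exons", "rank", "length", "count", "rate", "D"]
    )
    out = (
        df.groupby(["n_exons", "rank"])
        .agg(
            n_genes=("rate", "size"),
            mean_rate=("rate", "mean"),
            mean_D=("D", "mean"),
            n_D=("D", lambda s: s.notna().sum()),
        )
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Polymorphism residuals
# ---------------------------------------------------------------------------

def polymorphism_residuals(
    polymorphism_rate: pd.Series, predicted_score: pd.Series
) -> pd.Series:
    """Scaled residuals of per-gene polymorphism regressed on predicted
    mutation score (OLS residuals divided by their standard deviation).
    Genes under purifying selection should sit below the line (negative)."""
    joined = pd.concat(
        {"poly": polymorphism_rate, "score": predicted_score}, axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 genes")
    if joined["score"].std() == 0:
        raise ValueError("predicted scores have zero variance")
    X = sm.add_constant(joined["score"].to_numpy())
    res = sm.OLS(joined["poly"].to_numpy(), X).fit()
    resid = res.resid
    sd = resid.std(ddof=1)
    # a numerically-exact linear relation has only round-off residuals
    tol = 1e-10 * max(float(np.abs(joined["poly"]).max()), 1.0)
    scaled = resid / sd if sd > tol else np.zeros_like(resid)
    return pd.Series(scaled, index=joined.index, name="scaled_residual")
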