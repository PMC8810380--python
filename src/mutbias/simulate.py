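"""Synthetic genomes, epigenomic tracks and mutation sets with programmed
ground truth.

The generator emulates the structure the analysis pipeline consumes: a
gene-dense genome whose genes decompose into upstream/UTR/CDS/intron/
downstream features; per-base feature tracks whose gene-body levels differ
by gene class (e.g. an H3K4me1-like mark elevated in "essential" genes);
and mutation sets placed with per-base probability that is a linear
function of the tracks times an optional per-region-kind multiplier (e.g.
a programmed gene-body rate reduction). Everything is deterministic under
(config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mutbias.genome import (
    DEFAULT_FLANK,
    GENE_BODY_KINDS,
    KIND_CODES,
    FeatureTrack,
    GeneModel,
    GenicFeature,
    GenomeAnnotation,
    MutationSet,
    kind_code_arrays,
)
from mutbias.nullmodels import BASES, MutationSpectrum

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SyntheticGenomeConfig:
    """Layout and composition of a synthetic gene-dense genome.

    Lengths are drawn uniformly from the given (lo, hi) ranges; CDS exon
    lengths are rounded so each gene's total CDS length is a codon multiple
    with a start and a stop codon. ``gc`` gives the target GC fraction per
    region kind ('intergenic' covers everything outside gene bodies).
    """

    n_genes: int = 100
    n_chromosomes: int = 1
    exon_count_range: tuple[int, int] = (1, 5)
    exon_length_range: tuple[int, int] = (120, 400)
    intron_length_range: tuple[int, int] = (60, 300)
    utr5_prob: float = 0.8
    utr3_prob: float = 0.8
    utr5_length_range: tuple[int, int] = (30, 150)
    utr3_length_range: tuple[int, int] = (60, 250)
    intergenic_length_range: tuple[int, int] = (1500, 4500)
    gc: dict[str, float] = field(
        default_factory=lambda: {
            "cds": 0.44,
            "intron": 0.32,
            "utr5": 0.38,
            "utr3": 0.33,
            "intergenic": 0.32,
        }
    )
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def validate(self) -> None:
        for rng_ in (
            self.exon_length_range,
            self.intron_length_range,
            self.utr5_length_range,
            self.utr3_length_range,
            self.intergenic_length_range,
        ):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid length range {rng_}")
        if self.exon_count_range[0] < 1:
            raise ValueError("genes need at least one exon")
        for p in (self.utr5_prob, self.utr3_prob):
            if not 0 <= p <= 1:
                raise ValueError("UTR probabilities must lie in [0,1]")
        for k, v in self.gc.items():
            if not 0 < v < 1:
                raise ValueError(f"GC({k}) must lie in (0,1)")
        if self.n_genes < 0 or self.n_chromosomes < 1:
            raise ValueError("n_genes >= 0 and n_chromosomes >= 1 required")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)]) if n else ""


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons-2) non-stop codons + stop, with iid bases at target GC."""
    if n_codons < 2:
        raise ValueError("CDS needs at least start and stop codons")
    need = n_codons - 2
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    stop_ids = {48 + 0 * 4 + 0, 48 + 0 * 4 + 2, 48 + 2 * 4 + 0}  # TAA TAG TGA (T=3,A=0,G=2)
    kept: list[np.ndarray] = []
    got = 0
    while got < need:
        m = max(16, int((need - got) * 1.1) + 8)
        draw = rng.choice(4, size=(m, 3), p=p)
        ids = draw[:, 0] * 16 + draw[:, 1] * 4 + draw[:, 2]
        ok = ~np.isin(ids, list(stop_ids))
        sel = draw[ok][: need - got]
        kept.append(sel)
        got += sel.shape[0]
    body = (
        "".join(np.array(list(BASES))[np.concatenate(kept).ravel()]) if need else ""
    )
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + body + stop


def generate_genome(cfg: SyntheticGenomeConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Generate (sequences, annotation) satisfying the genome invariants."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1

    sequences: dict[str, str] = {}
    chrom_meta: list[tuple[str, int]] = []
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0
        chrom_genes: list[tuple[int, dict]] = []  # (gene start, plan)
        for _ in range(per_chrom[ci]):
            ig = int(rng.integers(*cfg.intergenic_length_range, endpoint=True))
            parts.append(_random_bases(rng, ig, cfg.gc["intergenic"]))
            cursor += ig
            plan = _plan_gene(rng, cfg)
            strand = "+" if rng.random() < 0.5 else "-"
            sense = _gene_sequence(rng, plan, cfg)
            gseq = sense if strand == "+" else sense.translate(_COMP)[::-1]
            chrom_genes.append((cursor, {"plan": plan, "strand": strand, "len": len(gseq)}))
            parts.append(gseq)
            cursor += len(gseq)
        tail = int(rng.integers(*cfg.intergenic_length_range, endpoint=True))
        parts.append(_random_bases(rng, tail, cfg.gc["intergenic"]))
        cursor += tail
        seq = "".join(parts)
        sequences[chrom] = seq
        chrom_meta.append((chrom, len(seq)))
        for start, meta in chrom_genes:
            gid += 1
            genes.append(
                _build_gene_model(
                    f"g{gid:05d}", chrom, start, meta["plan"], meta["strand"],
                    meta["len"], len(seq), cfg.flank,
                )
            )
    ann = GenomeAnnotation(chrom_meta, genes)
    ann.validate()
    return sequences, ann


def _plan_gene(rng: np.random.Generator, cfg: SyntheticGenomeConfig) -> dict:
    """Sense-orientation segment plan: lengths of utr5, cds exons, introns, utr3."""
    n_exons = int(rng.integers(*cfg.exon_count_range, endpoint=True))
    cds_lens = [int(rng.integers(*cfg.exon_length_range, endpoint=True)) for _ in range(n_exons)]
    total = sum(cds_lens)
    cds_lens[-1] += (3 - total % 3) % 3  # pad to codon multiple
    if sum(cds_lens) < 6:
        cds_lens[-1] += 6 - sum(cds_lens)
    intron_lens = [
        int(rng.integers(*cfg.intron_length_range, endpoint=True)) for _ in range(n_exons - 1)
    ]
    utr5 = (
        int(rng.integers(*cfg.utr5_length_range, endpoint=True))
        if rng.random() < cfg.utr5_prob
        else 0
    )
    utr3 = (
        int(rng.integers(*cfg.utr3_length_range, endpoint=True))
        if rng.random() < cfg.utr3_prob
        else 0
    )
    return {"utr5": utr5, "cds": cds_lens, "introns": intron_lens, "utr3": utr3}


def _gene_sequence(rng: np.random.Generator, plan: dict, cfg: SyntheticGenomeConfig) -> str:
    n_codons = sum(plan["cds"]) // 3
    cds_seq = _random_cds(rng, n_codons, cfg.gc["cds"])
    parts = [_random_bases(rng, plan["utr5"], cfg.gc["utr5"])]
    off = 0
    for i, ln in enumerate(plan["cds"]):
        parts.append(cds_seq[off : off + ln])
        off += ln
        if i < len(plan["introns"]):
            parts.append(_random_bases(rng, plan["introns"][i], cfg.gc["intron"]))
    parts.append(_random_bases(rng, plan["utr3"], cfg.gc["utr3"]))
    return "".join(parts)


def _build_gene_model(
    gene_id: str,
    chrom: str,
    start: int,
    plan: dict,
    strand: str,
    gene_len: int,
    chrom_len: int,
    flank: int,
) -> GeneModel:
    """Map the sense-orientation plan onto genome coordinates."""
    # sense-orientation feature list
    sense: list[tuple[str, int, int | None]] = []
    if plan["utr5"]:
        sense.append(("utr5", plan["utr5"], None))
    for i, ln in enumerate(plan["cds"]):
        sense.append(("cds", ln, i + 1))
        if i < len(plan["introns"]):
            sense.append(("intron", plan["introns"][i], i + 1))
    if plan["utr3"]:
        sense.append(("utr3", plan["utr3"], None))

    feats: list[GenicFeature] = []
    if strand == "+":
        off = start
        for kind, ln, rank in sense:
            feats.append(GenicFeature(kind, off, off + ln, rank))
            off += ln
        tss, tts = start, start + gene_len
        feats.append(GenicFeature("upstream", max(0, start - flank), start))
        feats.append(
            GenicFeature("downstream", start + gene_len, min(chrom_len, start + gene_len + flank))
        )
    else:
        off = start + gene_len  # sense 5' end is the right edge
        for kind, ln, rank in sense:
            feats.append(GenicFeature(kind, off - ln, off, rank))
            off -= ln
        tss, tts = start + gene_len, start
        feats.append(
            GenicFeature("upstream", start + gene_len, min(chrom_len, start + gene_len + flank))
        )
        feats.append(GenicFeature("downstream", max(0, start - flank), start))
    return GeneModel(gene_id, chrom, strand, tss, tts, feats)


# ---------------------------------------------------------------------------
# Feature tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSpec:
    """One synthetic track: mean signal by region kind, with optional
    gene-class overrides of the gene-body mean."""

    name: str
    region_means: dict[str, float] = field(
        default_factory=lambda: {"gene_body": 0.6, "intergenic": 0.2}
    )
    class_means: dict[str, float] = field(default_factory=dict)


@dataclass
class TrackGeneratorConfig:
    tracks: list[TrackSpec] = field(default_factory=list)
    gene_classes: dict[str, str] = field(default_factory=dict)  # gene_id -> label
    noise_sd: float = 0.05
    noise_correlation: float = 0.0  # shared-noise correlation between tracks

    def validate(self) -> None:
        if not 0 <= self.noise_correlation <= 1:
            raise ValueError("noise_correlation must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        valid = set(KIND_CODES) | {"gene_body"}
        for t in self.tracks:
            bad = set(t.region_means) - valid
            if bad:
                raise ValueError(f"track {t.name}: unknown region kinds {sorted(bad)}")


def generate_tracks(
    annotation: GenomeAnnotation,
    cfg: TrackGeneratorConfig,
    seed: int = 0,
) -> list[FeatureTrack]:
    """Per-base tracks: region-kind mean + gene-class contrast + Gaussian
    noise, clipped to [0, 1] (unit scale)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    lengths = annotation.chrom_lengths
    tracks = []
    shared = {c: rng.standard_normal(ln) for c, ln in lengths.items()} if cfg.noise_correlation else None
    for spec in cfg.tracks:
        means = {}
        base = spec.region_means.get("intergenic", 0.0)
        body_default = spec.region_means.get("gene_body")
        values = {c: np.full(ln, base, dtype=float) for c, ln in lengths.items()}
        # two passes so gene bodies are never overwritten by a neighbouring
        # gene's flank (flank means first, gene-body means second)
        for g in annotation.genes:
            arr = values[g.chrom]
            for f in g.features:
                if f.kind not in GENE_BODY_KINDS:
                    arr[f.start : f.end] = spec.region_means.get(f.kind, base)
        for g in annotation.genes:
            label = cfg.gene_classes.get(g.id)
            arr = values[g.chrom]
            for f in g.features:
                if f.kind in GENE_BODY_KINDS:
                    mean = spec.region_means.get(f.kind, body_default)
                    if mean is None:
                        mean = base
                    if label is not None and label in spec.class_means:
                        mean = spec.class_means[label]
                    arr[f.start : f.end] = mean
        if cfg.noise_sd > 0:
            rho = cfg.noise_correlation
            for c, ln in lengths.items():
                own = rng.standard_normal(ln)
                noise = (
                    np.sqrt(rho) * shared[c] + np.sqrt(1 - rho) * own if shared is not None else own
                )
                values[c] += cfg.noise_sd * noise
        for c in values:
            np.clip(values[c], 0.0, 1.0, out=values[c])
        tracks.append(FeatureTrack(spec.name, values, "unit"))
    return tracks


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@dataclass
class MutationGeneratorConfig:
    """Linear-rate mutation placement.

    Per-base relative rate = (baseline + sum_t coefficients[t] * track_t),
    clipped at 0, then multiplied by ``region_multiplier`` for the base's
    region kind ('gene_body' applies to all transcript-span kinds). ``n``
    mutations are then placed multinomially in proportion to that rate.
    """

    baseline_rate: float = 1.0
    coefficients: dict[str, float] = field(default_factory=dict)
    region_multiplier: dict[str, float] = field(default_factory=dict)
    snv_fraction: float = 0.9
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum)
    n_mutations: int = 10_000
    n_lines: int = 1
    het_fraction: float = 0.0
    qd: float = 40.0
    dp: int = 20

    def validate(self) -> None:
        if not 0 <= self.snv_fraction <= 1:
            raise ValueError("snv_fraction must lie in [0,1]")
        if self.n_mutations < 0 or self.n_lines < 1:
            raise ValueError("n_mutations >= 0 and n_lines >= 1 required")
        for k, v in self.region_multiplier.items():
            if k not in KIND_CODES and k != "gene_body":
                raise ValueError(f"unknown region kind {k!r}")
            if v < 0:
                raise ValueError("region multipliers must be non-negative")


def per_base_rate(
    annotation: GenomeAnnotation,
    tracks: list[FeatureTrack],
    cfg: MutationGeneratorConfig,
) -> tuple[dict[str, np.ndarray], int]:
    """The generator's per-base relative rate; returns (rates, n_clipped)."""
    track_by_name = {t.name: t for t in tracks}
    lengths = annotation.chrom_lengths
    rates = {c: np.full(ln, float(cfg.baseline_rate)) for c, ln in lengths.items()}
    for name, beta in cfg.coefficients.items():
        if name not in track_by_name:
            raise ValueError(f"coefficient refers to unknown track {name!r}")
        for c in rates:
            rates[c] += beta * track_by_name[name].values[c]
    n_clipped = 0
    for c in rates:
        neg = rates[c] < 0
        n_clipped += int(neg.sum())
        rates[c][neg] = 0.0
    if cfg.region_multiplier:
        codes = kind_code_arrays(annotation)
        mult_by_code = np.ones(7)
        if "gene_body" in cfg.region_multiplier:
            for k in GENE_BODY_KINDS:
                mult_by_code[KIND_CODES[k]] = cfg.region_multiplier["gene_body"]
        for k, v in cfg.region_multiplier.items():
            if k != "gene_body":
                mult_by_code[KIND_CODES[k]] = v
        for c in rates:
            rates[c] *= mult_by_code[codes[c]]
    return rates, n_clipped


def generate_mutations(
    annotation: GenomeAnnotation,
    sequences: dict[str, str],
    tracks: list[FeatureTrack],
    cfg: MutationGeneratorConfig,
    seed: int = 0,
) -> MutationSet:
    """Place mutations with probability proportional to the configured
    linear rate x region multiplier; SNV alts follow the spectrum
    conditioned on the reference base, indels are 1-bp events."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    rates, n_clipped = per_base_rate(annotation, tracks, cfg)
    if n_clipped:
        warnings.warn(f"{n_clipped} bases had negative linear rate, clipped to 0")
    chroms = sorted(rates)
    flat_rate = np.concatenate([rates[c] for c in chroms])
    total = flat_rate.sum()
    if total <= 0:
        raise ValueError("no mutable sites (all rates zero)")
    offsets = np.concatenate([[0], np.cumsum([rates[c].size for c in chroms])])
    flat = rng.choice(flat_rate.size, size=cfg.n_mutations, p=flat_rate / total)
    flat = np.sort(flat)
    ci = np.searchsorted(offsets, flat, side="right") - 1
    m = cfg.spectrum.alt_prob_matrix()
    cum = np.cumsum(m, axis=1)
    base_idx = {b: i for i, b in enumerate(BASES)}
    rows = []
    is_snv = rng.random(cfg.n_mutations) < cfg.snv_fraction
    u_alt = rng.random(cfg.n_mutations)
    lines = rng.integers(0, cfg.n_lines, size=cfg.n_mutations)
    het = rng.random(cfg.n_mutations) < cfg.het_fraction
    for k in range(cfg.n_mutations):
        chrom = chroms[ci[k]]
        pos = int(flat[k] - offsets[ci[k]])
        seq = sequences[chrom]
        ref = seq[pos]
        if is_snv[k]:
            alt = BASES[int((cum[base_idx[ref]] < u_alt[k]).sum())]
            vtype = "SNV"
        else:
            if u_alt[k] < 0.5:  # 1-bp insertion after pos
                alt = ref + BASES[int(rng.integers(4))]
            elif pos + 1 < len(seq):  # 1-bp deletion of the next base
                ref = seq[pos : pos + 2]
                alt = ref[0]
            else:
                alt = ref + BASES[int(rng.integers(4))]
            vtype = "indel"
        rows.append(
            (
                chrom, pos, ref, alt, vtype, f"L{lines[k] + 1:03d}",
                "het" if het[k] else "hom", cfg.qd, float(cfg.dp), None,
            )
        )
    return MutationSet(
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "type", "line",
                                    "zygosity", "qd", "dp", "origin"])
    )


# ---------------------------------------------------------------------------
# Direct region-table simulation (regression-design experiments)
# ---------------------------------------------------------------------------

def simulate_region_table(
    n_regions: int,
    signal_betas: dict[str, float],
    n_noise_predictors: int = 10,
    baseline: float = 1.0,
    n_mutations: int = 20_000,
    region_length: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a region feature table with a known linear rate law.

    Predictors are iid uniform [0, 1]. The true per-bp relative rate is
    ``baseline + sum_j beta_j x_j`` (clipped at 0); ``n_mutations`` events
    are placed multinomially over regions in proportion to rate x length.
    Returns a frame with predictors, ``length``, ``snv_count``,
    ``snv_rate`` (count/length) and the latent ``true_rate`` column
    (relative per-bp rate, for recovery checks).
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for name in signal_betas:
        cols[name] = rng.random(n_regions)
    for j in range(n_noise_predictors):
        cols[f"noise_{j + 1}"] = rng.random(n_regions)
    df = pd.DataFrame(cols)
    rate = np.full(n_regions, float(baseline))
    for name, beta in signal_betas.items():
        rate = rate + beta * df[name].to_numpy()
    rate = np.clip(rate, 0, None)
    df["length"] = region_length
    weights = rate * df["length"].to_numpy()
    if weights.sum() <= 0:
        raise ValueError("all-zero rates")
    counts = rng.multinomial(n_mutations, weights / weights.sum())
    df["snv_count"] = counts
    df["snv_rate"] = counts / df["length"]
    df["true_rate"] = rate
    return df
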