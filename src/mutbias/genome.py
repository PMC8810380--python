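"""Genome I/O and genic-feature decomposition.

All coordinates are stored 0-based half-open; GFF3 (1-based inclusive) and
VCF (1-based) are converted at the boundary. Each gene is reduced to one
canonical transcript (the longest mRNA) and decomposed into strand-aware
genic features: a fixed upstream flank, 5' UTR, CDS exons with rank, introns
with rank, 3' UTR and a fixed downstream flank. Ranks count 1..k in
transcription (5'->3') order, so on minus-strand genes rank 1 is the
rightmost CDS segment in genome coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("upstream", "utr5", "cds", "intron", "utr3", "downstream")
#: kinds making up the transcript span (flanks excluded)
GENE_BODY_KINDS = ("utr5", "cds", "intron", "utr3")

DEFAULT_FLANK = 3000


@dataclass(frozen=True)
class GenicFeature:
    """One genic-feature instance: a ``kind`` over ``[start, end)``."""

    kind: str
    start: int
    end: int
    rank: int | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError(f"negative-length feature {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A canonical gene model with its genic-feature decomposition.

    ``tss``/``tts`` are the transcription start/termination coordinates:
    for a + strand gene tss < tts, for a - strand gene tss > tts (both are
    0-based positions on the forward strand; tss of a minus gene is the
    half-open end of its span).
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    features: list[GenicFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def start(self) -> int:
        """Transcript span start (genome orientation)."""
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.end - self.start

    def features_of(self, kind: str) -> list[GenicFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def n_cds_exons(self) -> int:
        return len(self.features_of("cds"))


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus decomposed gene models."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.id} outside chromosome bounds")
            for kind in ("cds", "intron"):
                ranks = sorted(f.rank for f in g.features_of(kind))
                if ranks and ranks != list(range(1, len(ranks) + 1)):
                    raise ValueError(f"gene {g.id}: non-contiguous {kind} ranks {ranks}")

    def feature_frame(self) -> pd.DataFrame:
        """All feature instances as a tidy frame (one row per instance)."""
        rows = [
            (g.id, g.chrom, g.strand, f.kind, f.rank, f.start, f.end, f.length)
            for g in self.genes
            for f in g.features
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "strand", "kind", "rank", "start", "end", "length"],
        )


@dataclass(frozen=True)
class VariantRecord:
    """One variant call in one line/sample (positions 0-based internally)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    type: str  # "SNV" | "indel"
    line: str
    zygosity: str  # "hom" | "het"
    qd: float = float("nan")
    dp: float = float("nan")
    origin: str | None = None


_MUTSET_COLUMNS = ["chrom", "pos", "ref", "alt", "type", "line", "zygosity", "qd", "dp", "origin"]


class MutationSet:
    """A set of per-line variant records, backed by a DataFrame.

    Columns: chrom, pos (0-based), ref, alt, type (SNV/indel), line,
    zygosity (hom/het), qd, dp, origin (germline/somatic/None).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _MUTSET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"MutationSet frame missing columns {missing}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "MutationSet":
        rows = [
            (r.chrom, r.pos, r.ref, r.alt, r.type, r.line, r.zygosity, r.qd, r.dp, r.origin)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=_MUTSET_COLUMNS))

    @classmethod
    def empty(cls) -> "MutationSet":
        return cls(pd.DataFrame(columns=_MUTSET_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[VariantRecord]:
        return [
            VariantRecord(
                r.chrom, int(r.pos), r.ref, r.alt, r.type, r.line, r.zygosity,
                float(r.qd) if pd.notna(r.qd) else float("nan"),
                float(r.dp) if pd.notna(r.dp) else float("nan"),
                r.origin if pd.notna(r.origin) else None,
            )
            for r in self.df.itertuples()
        ]

    def subset(self, mask) -> "MutationSet":
        return MutationSet(self.df[np.asarray(mask)].reset_index(drop=True))

    def positions_on(self, chrom: str) -> np.ndarray:
        return np.sort(self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64))


@dataclass
class FeatureTrack:
    """Dense per-base numeric signal over each chromosome."""

    name: str
    values: dict[str, np.ndarray]
    scale: str = "raw"  # "raw" | "unit"

    def unit_scaled(self) -> "FeatureTrack":
        """Divide by the genome-wide maximum so values lie in [0, 1]."""
        m = max((float(v.max()) for v in self.values.values() if v.size), default=0.0)
        if m <= 0:
            return FeatureTrack(self.name, {c: v.astype(float) for c, v in self.values.items()}, "unit")
        return FeatureTrack(self.name, {c: v / m for c, v in self.values.items()}, "unit")

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        v = self.values[chrom]
        if start < 0 or end > v.size:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside track {self.name} (len {v.size})"
            )
        if end == start:
            return 0.0
        return float(v[start:end].mean())


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def _decompose_transcript(
    strand: str,
    t_start: int,
    t_end: int,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    utr5: list[tuple[int, int]],
    utr3: list[tuple[int, int]],
    chrom_length: int,
    flank: int,
) -> list[GenicFeature]:
    """Build ranked genic features from transcript sub-intervals.

    Intervals are 0-based half-open in genome orientation; ranks are assigned
    in transcription order.
    """
    exons = sorted(exons)
    cds = sorted(cds)
    feats: list[GenicFeature] = []

    introns = [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1]
    ]

    order = 1 if strand == "+" else -1
    for rank, (s, e) in enumerate(cds[::order], start=1):
        feats.append(GenicFeature("cds", s, e, rank))
    for rank, (s, e) in enumerate(introns[::order], start=1):
        feats.append(GenicFeature("intron", s, e, rank))
    for s, e in utr5:
        feats.append(GenicFeature("utr5", s, e))
    for s, e in utr3:
        feats.append(GenicFeature("utr3", s, e))

    if strand == "+":
        up = (max(0, t_start - flank), t_start)
        down = (t_end, min(chrom_length, t_end + flank))
    else:
        up = (t_end, min(chrom_length, t_end + flank))
        down = (max(0, t_start - flank), t_start)
    feats.append(GenicFeature("upstream", *up))
    feats.append(GenicFeature("downstream", *down))
    return feats


def load_annotation(
    path: str,
    chrom_lengths: dict[str, int] | None = None,
    flank: int = DEFAULT_FLANK,
) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    One canonical transcript (the longest mRNA) is kept per gene. Introns are
    derived as gaps between exons. ``chrom_lengths`` overrides or supplements
    ``##sequence-region`` directives; upstream/downstream flanks of ``flank``
    bp are attached without truncation at neighbouring genes.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )

    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                lengths[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    if chrom_lengths:
        lengths.update(chrom_lengths)

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            warnings.warn(f"gene {gene.id} has no mRNA child; skipped")
            continue
        mrna = max(mrnas, key=lambda m: m.end - m.start)
        exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        utr5 = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")]
        utr3 = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")]
        if not exons:
            exons = sorted(cds + utr5 + utr3)
        t_start, t_end = mrna.start - 1, mrna.end
        chrom = gene.seqid
        if chrom not in lengths:
            raise ValueError(f"no length known for chromosome {chrom}")
        strand = gene.strand
        if strand not in "+-":
            warnings.warn(f"gene {gene.id} has strand {strand!r}; skipped")
            continue
        feats = _decompose_transcript(
            strand, t_start, t_end, exons, cds, utr5, utr3, lengths[chrom], flank
        )
        tss, tts = (t_start, t_end) if strand == "+" else (t_end, t_start)
        genes.append(GeneModel(gene.id, chrom, strand, tss, tts, feats))

    chroms = sorted(lengths.items())
    ann = GenomeAnnotation(chroms, genes)
    ann.validate()
    return ann


def write_gff3(annotation: GenomeAnnotation, sequences_or_lengths, path: str) -> None:
    """Write an annotation as GFF3 (gene/mRNA/exon/CDS/UTR records)."""
    if hasattr(sequences_or_lengths, "items"):
        first = next(iter(sequences_or_lengths.values()), "")
        if isinstance(first, str):
            lengths = {c: len(s) for c, s in sequences_or_lengths.items()}
        else:
            lengths = dict(sequences_or_lengths)
    else:
        lengths = dict(sequences_or_lengths)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, ln in sorted(lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {ln}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            body = [f for f in g.features if f.kind in GENE_BODY_KINDS]
            s, e = g.start + 1, g.end  # to 1-based inclusive
            fh.write(f"{g.chrom}\t.\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.id}\n")
            mid = f"{g.id}.1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mid};Parent={g.id}\n")
            kinds = {"utr5": "five_prime_UTR", "cds": "CDS", "utr3": "three_prime_UTR"}
            exonic = sorted(
                (f for f in body if f.kind in ("utr5", "cds", "utr3")),
                key=lambda f: f.start,
            )
            # exons = maximal runs of adjacent exonic features
            runs: list[list[int]] = []
            for f in exonic:
                if runs and runs[-1][1] == f.start:
                    runs[-1][1] = f.end
                else:
                    runs.append([f.start, f.end])
            for i, (rs, re_) in enumerate(runs, 1):
                fh.write(
                    f"{g.chrom}\t.\texon\t{rs + 1}\t{re_}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
            for f in exonic:
                phase = "0" if f.kind == "cds" else "."
                fh.write(
                    f"{g.chrom}\t.\t{kinds[f.kind]}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{g.strand}\t{phase}\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    from pyfaidx import Fasta

    fa = Fasta(path, as_raw=True, sequence_always_upper=True, build_index=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tracks: bedGraph / BED
# ---------------------------------------------------------------------------

def load_track(
    path: str,
    chrom_lengths: dict[str, int],
    name: str | None = None,
    unit_scale: bool = False,
) -> FeatureTrack:
    """Load a bedGraph (4th column = value) or BED peak file (value 1.0).

    Returns a dense per-base track; uncovered bases are 0. Intervals beyond
    the chromosome end raise. With ``unit_scale`` the result is divided by
    its genome-wide maximum.
    """
    values = {c: np.zeros(ln, dtype=float) for c, ln in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            try:
                val = float(parts[3]) if len(parts) > 3 else 1.0
            except ValueError:
                val = 1.0  # BED name column -> indicator track
            if chrom not in values:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start < 0 or end > values[chrom].size:
                raise ValueError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} beyond chromosome end"
                )
            values[chrom][start:end] = val
    track = FeatureTrack(name or path, values, "raw")
    return track.unit_scaled() if unit_scale else track


def write_bedgraph(track: FeatureTrack, path: str) -> None:
    """Write a dense track as run-length-compressed bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if v.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [v.size]])
            for s, e in zip(starts, ends):
                val = v[s]
                if val != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:g}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_variants(path: str) -> MutationSet:
    """Read a VCF into a :class:`MutationSet`: one record per sample carrying
    a non-reference genotype. Multi-allelic sites are split per alt allele;
    missing genotypes are skipped. QD and DP are taken from INFO.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    n_missing = 0
    for v in vcf:
        qd = v.INFO.get("QD")
        dp = v.INFO.get("DP")
        qd = float(qd) if qd is not None else float("nan")
        dp = float(dp) if dp is not None else float("nan")
        for si, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                n_missing += 1
                continue
            alts = {a for a in (a0, a1) if a > 0}
            for ai in alts:
                alt = v.ALT[ai - 1]
                vtype = "SNV" if len(v.REF) == 1 and len(alt) == 1 else "indel"
                zyg = "hom" if a0 == a1 else "het"
                rows.append(
                    (v.CHROM, v.POS - 1, v.REF, alt, vtype, samples[si], zyg, qd, dp, None)
                )
    if n_missing:
        warnings.warn(f"{n_missing} missing genotypes skipped in {path}")
    if not rows:
        return MutationSet.empty()
    return MutationSet(pd.DataFrame(rows, columns=_MUTSET_COLUMNS))


def write_variants(
    mutations: MutationSet,
    path: str,
    chrom_lengths: dict[str, int] | None = None,
    samples: list[str] | None = None,
) -> None:
    """Write a MutationSet as VCF 4.2 (supported subset: QD/DP INFO, GT).

    Each record's line id becomes a sample column; hom-alt -> ``1/1``,
    het -> ``0/1``, absence -> ``0/0``.
    """
    df = mutations.df
    if samples is None:
        samples = sorted(df["line"].unique()) if len(df) else []
    sample_idx = {s: i for i, s in enumerate(samples)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for c, ln in sorted(chrom_lengths.items()):
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        if not len(df):
            return
        for (chrom, pos, ref, alt), grp in df.groupby(
            ["chrom", "pos", "ref", "alt"], sort=True
        ):
            gts = ["0/0"] * len(samples)
            for r in grp.itertuples():
                gts[sample_idx[r.line]] = "1/1" if r.zygosity == "hom" else "0/1"
            first = grp.iloc[0]
            info = []
            if pd.notna(first["qd"]):
                info.append(f"QD={first['qd']:g}")
            if pd.notna(first["dp"]):
                info.append(f"DP={int(first['dp'])}")
            info_s = ";".join(info) if info else "."
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t{info_s}\tGT\t" + "\t".join(gts) + "\n"
            )


# Per-base region-kind codes. Higher-priority kinds are painted last so a
# base covered by both a flank of one gene and the CDS of another is coded CDS.
KIND_CODES = {
    "intergenic": 0,
    "upstream": 1,
    "downstream": 2,
    "intron": 3,
    "utr5": 4,
    "utr3": 5,
    "cds": 6,
}
_PAINT_ORDER = ("upstream", "downstream", "intron", "utr5", "utr3", "cds")
#: codes counting as gene body (transcript span kinds)
GENE_BODY_CODES = frozenset(KIND_CODES[k] for k in GENE_BODY_KINDS)


def kind_code_arrays(annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    """Per-base region-kind code array for each chromosome (see KIND_CODES)."""
    out = {c: np.zeros(ln, dtype=np.int8) for c, ln in annotation.chromosomes}
    for kind in _PAINT_ORDER:
        code = KIND_CODES[kind]
        for g in annotation.genes:
            arr = out[g.chrom]
            for f in g.features:
                if f.kind == kind:
                    arr[f.start : f.end] = code
    return out


def gc_content(seq: str) -> float:
    """GC fraction of a sequence (N bases excluded from the denominator)."""
    if not seq:
        return float("nan")
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else float("nan")
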