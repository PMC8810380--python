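"""Per-region predictor aggregation: the mutation model's design matrix.

One row per genic-feature instance (gene id, kind, rank), carrying region
length, GC fraction, methylated-cytosine counts per bp by context
(CG/CHG/CHH), the region mean of each unit-scaled epigenomic track,
gene-level expression broadcast to the gene's regions, and observed
SNV/indel counts and per-bp rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mutbias.genome import FeatureTrack, GenomeAnnotation, MutationSet, gc_content

METHYLATION_CONTEXTS = ("CG", "CHG", "CHH")


def classify_methylation_context(seq: str, pos: int) -> str | None:
    """CG/CHG/CHH context of a cytosine at ``pos`` (forward strand), or the
    strand-symmetric context of a guanine; None for other bases/edges."""
    b = seq[pos]
    if b == "C":
        n1 = seq[pos + 1] if pos + 1 < len(seq) else ""
        n2 = seq[pos + 2] if pos + 2 < len(seq) else ""
        if n1 == "G":
            return "CG"
        if n1 in "ACT" and n2 == "G":
            return "CHG"
        if n1 in "ACT" and n2 in "ACT":
            return "CHH"
        return None
    if b == "G":
        n1 = seq[pos - 1] if pos - 1 >= 0 else ""
        n2 = seq[pos - 2] if pos - 2 >= 0 else ""
        if n1 == "C":
            return "CG"
        if n1 in "AGT" and n2 == "C":
            return "CHG"
        if n1 in "AGT" and n2 in "AGT":
            return "CHH"
        return None
    return None


def aggregate_features(
    annotation: GenomeAnnotation,
    sequences: dict[str, str],
    tracks: list[FeatureTrack],
    methylation: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    impute_expression: bool = False,
) -> pd.DataFrame:
    """Build the region feature table.

    ``methylation``: frame with columns chrom, pos (0-based), context
    (CG/CHG/CHH), one row per methylated cytosine. ``expression``: frame
    indexed by or containing ``gene_id`` with an ``expression`` column.
    Genes without expression data get NaN (rows later dropped by the model)
    unless ``impute_expression`` replaces them with the mean.
    """
    rows = []
    track_prefix = [(t.name, t if t.scale == "unit" else t.unit_scaled()) for t in tracks]
    prefixes = {
        name: {c: np.concatenate([[0.0], np.cumsum(v)]) for c, v in t.values.items()}
        for name, t in track_prefix
    }
    meth_sorted: dict[tuple[str, str], np.ndarray] = {}
    if methylation is not None:
        for (chrom, ctx), grp in methylation.groupby(["chrom", "context"]):
            meth_sorted[(chrom, ctx)] = np.sort(grp["pos"].to_numpy(dtype=np.int64))

    for g in annotation.genes:
        seq = sequences[g.chrom]
        for f in g.features:
            if f.length == 0:
                continue
            row = {
                "gene_id": g.id,
                "kind": f.kind,
                "rank": f.rank,
                "chrom": g.chrom,
                "start": f.start,
                "end": f.end,
                "length": f.length,
                "gc": gc_content(seq[f.start : f.end]),
            }
            for name, pre in prefixes.items():
                p = pre[g.chrom]
                if f.end >= p.size:
                    raise ValueError(f"region {g.chrom}:{f.start}-{f.end} outside track {name}")
                row[name] = (p[f.end] - p[f.start]) / f.length
            for ctx in METHYLATION_CONTEXTS:
                pos = meth_sorted.get((g.chrom, ctx))
                if pos is None:
                    row[f"m{ctx}"] = 0.0
                else:
                    n = np.searchsorted(pos, f.end) - np.searchsorted(pos, f.start)
                    row[f"m{ctx}"] = n / f.length
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return table

    if expression is not None:
        expr = expression.reset_index()
        if "gene_id" not in expr.columns or "expression" not in expr.columns:
            raise ValueError("expression frame needs gene_id and expression columns")
        table = table.merge(expr[["gene_id", "expression"]], on="gene_id", how="left")
        if impute_expression:
            table["expression"] = table["expression"].fillna(table["expression"].mean())
    for col in ("snv_count", "indel_count"):
        table[col] = 0
    for col in ("snv_rate", "indel_rate"):
        table[col] = 0.0
    return table


def count_mutations(
    table: pd.DataFrame,
    mutations: MutationSet,
) -> pd.DataFrame:
    """Fill observed SNV/indel counts and per-bp rates into the table.

    A mutation is counted in every region containing its position, so
    overlapping regions (e.g. a flank reaching into a neighbouring gene)
    each count it. Returns a new frame; aggregation is linear in the
    mutation set.
    """
    out = table.copy()
    pos_by = {
        ("SNV", c): np.sort(g["pos"].to_numpy(np.int64))
        for c, g in mutations.df[mutations.df["type"] == "SNV"].groupby("chrom")
    }
    pos_by.update(
        {
            ("indel", c): np.sort(g["pos"].to_numpy(np.int64))
            for c, g in mutations.df[mutations.df["type"] == "indel"].groupby("chrom")
        }
    )
    for vtype, col in (("SNV", "snv_count"), ("indel", "indel_count")):
        counts = np.zeros(len(out), dtype=np.int64)
        for i, (chrom, start, end) in enumerate(
            zip(out["chrom"], out["start"], out["end"])
        ):
            pos = pos_by.get((vtype, chrom))
            if pos is not None:
                counts[i] = np.searchsorted(pos, end) - np.searchsorted(pos, start)
        out[col] = counts
    out["snv_rate"] = out["snv_count"] / out["length"]
    out["indel_rate"] = out["indel_count"] / out["length"]
    return out


def gene_level(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Length-weighted gene-level means of the given columns."""
    def agg(grp: pd.DataFrame) -> pd.Series:
        w = grp["length"].to_numpy(float)
        return pd.Series({c: np.average(grp[c].to_numpy(float), weights=w) for c in columns})

    out = table.groupby("gene_id").apply(agg, include_groups=False)
    return out
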