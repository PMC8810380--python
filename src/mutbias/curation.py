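"""Variant filtering and germline/somatic classification for
mutation-accumulation call sets.

Three rules are applied, mirroring standard MA-line curation:

* quality — retain calls with QD > 30 and DP > 3 (strict; missing values
  fail conservatively);
* mappability — drop calls with any base of mappability below threshold
  within +/-100 bp (inclusive window);
* origin — within a founder group, a variant homozygous in exactly one
  line is germline, heterozygous in exactly one line is somatic, and a
  variant shared by more lines than allowed is removed (likely inherited
  standing variation or a systematic artefact).

All filters are idempotent and commute; a removal log attributes each
dropped record to exactly one rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mutbias.genome import FeatureTrack, MutationSet


@dataclass
class CurationConfig:
    qd_min: float = 30.0
    dp_min: int = 3
    mappability_flank: int = 100
    mappability_threshold: float = 1.0
    max_lines_sharing: int = 1

    def __post_init__(self):
        if min(self.qd_min, self.dp_min, self.mappability_flank,
               self.mappability_threshold, self.max_lines_sharing) < 0:
            raise ValueError("curation thresholds must be non-negative")


@dataclass
class CurationLog:
    """Per-rule removal counts accumulated across filter calls."""

    removed: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + int(n)

    @property
    def total(self) -> int:
        return sum(self.removed.values())


def filter_quality(
    variants: MutationSet,
    cfg: CurationConfig | None = None,
    log: CurationLog | None = None,
) -> MutationSet:
    """Retain records with QD > qd_min AND DP > dp_min (strict).

    Missing QD or DP fails the filter.
    """
    cfg = cfg or CurationConfig()
    df = variants.df
    qd = pd.to_numeric(df["qd"], errors="coerce")
    dp = pd.to_numeric(df["dp"], errors="coerce")
    keep = (qd > cfg.qd_min) & (dp > cfg.dp_min)
    keep = keep.fillna(False).to_numpy()
    if log is not None:
        log.add("quality", (~keep).sum())
    return variants.subset(keep)


def filter_mappability(
    variants: MutationSet,
    mappability: FeatureTrack,
    cfg: CurationConfig | None = None,
    log: CurationLog | None = None,
) -> MutationSet:
    """Remove a variant iff any base within +/-flank bp (inclusive, clipped
    at chromosome ends) has mappability below the threshold."""
    cfg = cfg or CurationConfig()
    # per-chromosome prefix counts of low-mappability bases
    low_prefix = {}
    for chrom, v in mappability.values.items():
        low = (v < cfg.mappability_threshold).astype(np.int64)
        low_prefix[chrom] = np.concatenate([[0], np.cumsum(low)])
    keep = np.ones(len(variants.df), dtype=bool)
    for i, r in enumerate(variants.df.itertuples()):
        if r.chrom not in low_prefix:
            raise ValueError(f"variant on {r.chrom} outside mappability track")
        pre = low_prefix[r.chrom]
        n = pre.size - 1
        if not 0 <= r.pos < n:
            raise ValueError(f"variant position {r.chrom}:{r.pos} outside track")
        lo = max(0, r.pos - cfg.mappability_flank)
        hi = min(n, r.pos + cfg.mappability_flank + 1)
        keep[i] = (pre[hi] - pre[lo]) == 0
    if log is not None:
        log.add("mappability", (~keep).sum())
    return variants.subset(keep)


def classify_origin(
    variants: MutationSet,
    line_groups: dict[str, str],
    cfg: CurationConfig | None = None,
    log: CurationLog | None = None,
) -> MutationSet:
    """Assign germline/somatic origin labels within founder groups.

    Within each group of MA lines descended from one founder, a site where
    exactly one line carries a homozygous alternative allele is a germline
    mutation; exactly one heterozygous line is a somatic mutation; a site
    shared by more than ``max_lines_sharing`` lines of the group is removed.
    """
    cfg = cfg or CurationConfig()
    df = variants.df.copy()
    unknown = set(df["line"]) - set(line_groups)
    if unknown:
        raise ValueError(f"lines absent from group mapping: {sorted(unknown)}")
    df["_group"] = df["line"].map(line_groups)
    origin = np.array([None] * len(df), dtype=object)
    keep = np.ones(len(df), dtype=bool)
    grouped = df.groupby(["_group", "chrom", "pos", "ref", "alt"], sort=False)
    for _, idx in grouped.groups.items():
        idx = np.asarray(df.index.get_indexer(idx))
        n_lines = df.iloc[idx]["line"].nunique()
        if n_lines > cfg.max_lines_sharing:
            keep[idx] = False
            continue
        for i in idx:
            origin[i] = "germline" if df.iloc[i]["zygosity"] == "hom" else "somatic"
    if log is not None:
        log.add("shared", (~keep).sum())
    df["origin"] = origin
    df = df.drop(columns="_group")
    return MutationSet(df[keep].reset_index(drop=True))


def curate(
    variants: MutationSet,
    mappability: FeatureTrack | None = None,
    line_groups: dict[str, str] | None = None,
    cfg: CurationConfig | None = None,
) -> tuple[MutationSet, CurationLog]:
    """Apply the full curation chain; returns (curated set, removal log)."""
    cfg = cfg or CurationConfig()
    log = CurationLog()
    out = filter_quality(variants, cfg, log)
    if mappability is not None:
        out = filter_mappability(out, mappability, cfg, log)
    if line_groups is not None:
        out = classify_origin(out, line_groups, cfg, log)
    return out, log
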