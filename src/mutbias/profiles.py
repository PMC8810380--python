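"""Metagene profiles: binned means of any per-position quantity at
transcription-oriented offsets from TSS or TTS, with bootstrap bands.

Offsets are oriented: negative = upstream of the anchor in transcription
direction, so minus-strand genes are flipped. Genes shorter than the
flank contribute gene-body bins only up to their own length (no
renormalization); bins reaching past a chromosome end are masked for that
gene. Event inputs (mutations, polymorphic positions) are converted to
per-bp rates before averaging; value inputs (tracks, windowed statistics)
are bin-averaged, with undefined values (e.g. Tajima's D where S = 0)
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from mutbias.genome import FeatureTrack, GenomeAnnotation, MutationSet


@dataclass
class ProfileCurve:
    """Binned metagene curve with a bootstrap +/-2 s.e.m. band."""

    anchor: str
    offsets: np.ndarray  # bin centers, bp
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: np.ndarray  # genes contributing per bin
    n_boot: int
    per_gene: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "offset": self.offsets,
                "mean": self.mean,
                "lo": self.lo,
                "hi": self.hi,
                "n": self.n,
            }
        )

    def mean_over(self, lo_bp: float, hi_bp: float) -> float:
        """Mean of bin means whose centers lie in [lo_bp, hi_bp)."""
        sel = (self.offsets >= lo_bp) & (self.offsets < hi_bp)
        return float(np.nanmean(self.mean[sel]))

    def plot(self, ax=None, label: str | None = None, color=None):
        """Basic curve plot with the +/-2 s.e.m. band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.offsets, self.lo, self.hi, alpha=0.3, color=color)
        ax.plot(self.offsets, self.mean, label=label, color=color)
        ax.axvline(0, ls=":", lw=0.8, color="grey")
        ax.set_xlabel(f"distance from {self.anchor} (bp)")
        return ax


def _gene_bin_matrix(
    annotation: GenomeAnnotation,
    anchor: str,
    flank: int,
    bin_size: int,
    fill,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Per-(gene, bin) value matrix scaffold with gene-length/edge masking.

    Returns (matrix filled by ``fill(gene, p0, p1) -> value or nan``,
    genes, bin centers). Bin b covers transcription offsets
    [-flank + b*bin, -flank + (b+1)*bin).
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin size")
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    n_bins = 2 * flank // bin_size
    offs0 = -flank + np.arange(n_bins) * bin_size  # bin start offsets
    centers = offs0 + bin_size / 2
    lengths = annotation.chrom_lengths
    M = np.full((len(annotation.genes), n_bins), np.nan)
    for gi, g in enumerate(annotation.genes):
        a = g.tss if anchor == "TSS" else g.tts
        clen = lengths[g.chrom]
        glen = g.length
        for b in range(n_bins):
            o0, o1 = offs0[b], offs0[b] + bin_size
            # gene-body truncation: offsets past the other end of the gene
            if anchor == "TSS" and o0 >= glen:
                continue
            if anchor == "TTS" and o1 <= -glen:
                continue
            if g.strand == "+":
                p0, p1 = a + o0, a + o1
            else:
                p0, p1 = a - o1, a - o0
            if p0 < 0 or p1 > clen:
                continue
            M[gi, b] = fill(g, p0, p1)
    return M, annotation.genes, centers


def _bootstrap_band(M: np.ndarray, n_boot: int, seed: int):
    import warnings as _w

    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, M.shape[1]))
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(M, axis=0)
        for r in range(n_boot):
            idx = rng.integers(0, M.shape[0], size=M.shape[0])
            reps[r] = np.nanmean(M[idx], axis=0)
        sem = np.nanstd(reps, axis=0, ddof=1)
    n_per_bin = np.sum(~np.isnan(M), axis=0)
    return mean, mean - 2 * sem, mean + 2 * sem, n_per_bin


def metagene_profile(
    data,
    annotation: GenomeAnnotation,
    anchor: str = "TSS",
    flank: int = 3000,
    bin_size: int = 100,
    n_boot: int = 100,
    seed: int = 0,
    value_column: str = "D",
) -> ProfileCurve:
    """Metagene profile of ``data`` around TSS or TTS.

    ``data`` may be a :class:`MutationSet` or dict of per-chromosome event
    positions (binned to per-bp rates), a :class:`FeatureTrack` (per-base
    values, bin-averaged), or a windowed-statistics DataFrame with columns
    chrom/start/end plus ``value_column`` (window values assigned to window
    midpoints; NaN windows skipped).
    """
    if isinstance(data, MutationSet):
        positions = {
            c: np.sort(g["pos"].to_numpy(np.int64)) for c, g in data.df.groupby("chrom")
        }
        fill = _event_fill(positions)
    elif isinstance(data, dict):
        positions = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in data.items()}
        fill = _event_fill(positions)
    elif isinstance(data, FeatureTrack):
        prefix = {
            c: np.concatenate([[0.0], np.cumsum(v)]) for c, v in data.values.items()
        }

        def fill(g, p0, p1):
            p = prefix[g.chrom]
            return (p[p1] - p[p0]) / (p1 - p0)

    elif isinstance(data, pd.DataFrame):
        mids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c, grp in data.dropna(subset=[value_column]).groupby("chrom"):
            m = ((grp["start"] + grp["end"]) // 2).to_numpy(np.int64)
            order = np.argsort(m)
            mids[c] = (m[order], grp[value_column].to_numpy(float)[order])

        def fill(g, p0, p1):
            if g.chrom not in mids:
                return np.nan
            m, v = mids[g.chrom]
            lo, hi = np.searchsorted(m, [p0, p1])
            if hi == lo:
                return np.nan
            return float(v[lo:hi].mean())

    else:
        raise TypeError(f"unsupported profile input {type(data)!r}")

    M, genes, centers = _gene_bin_matrix(annotation, anchor, flank, bin_size, fill)
    mean, lo, hi, n = _bootstrap_band(M, n_boot, seed)
    return ProfileCurve(anchor, centers, mean, lo, hi, n, n_boot, per_gene=M)


def _event_fill(positions: dict[str, np.ndarray]):
    def fill(g, p0, p1):
        pos = positions.get(g.chrom)
        if pos is None:
            return 0.0
        c = np.searchsorted(pos, p1) - np.searchsorted(pos, p0)
        return c / (p1 - p0)

    return fill


@dataclass
class AgreementReport:
    """Agreement between two curves over the same bins."""

    r: float
    r_squared: float
    n_bins: int


def compare_curves(a: ProfileCurve, b: ProfileCurve) -> AgreementReport:
    """Pearson r between two curves and R^2 from regressing b on a."""
    if a.offsets.shape != b.offsets.shape or not np.allclose(a.offsets, b.offsets):
        raise ValueError("curves have different offsets")
    ok = ~(np.isnan(a.mean) | np.isnan(b.mean))
    x, y = a.mean[ok], b.mean[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 common bins")
    if x.std() == 0 or y.std() == 0:
        return AgreementReport(float("nan"), float("nan"), int(x.size))
    r, _ = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1 - resid.var() / y.var()
    return AgreementReport(float(r), float(r2), int(x.size))


@dataclass
class GroupMean:
    label: str
    mean: float
    lo: float
    hi: float
    n: int


def bootstrap_group_mean(
    statistic: pd.Series,
    labels: pd.Series,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean with bootstrap +/-2 s.e.m. band (resampling genes
    within each group)."""
    rng = np.random.default_rng(seed)
    joined = pd.concat({"x": statistic, "g": labels}, axis=1).dropna()
    rows = []
    for label, grp in joined.groupby("g"):
        x = grp["x"].to_numpy(float)
        if x.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 members")
        reps = np.array(
            [x[rng.integers(0, x.size, size=x.size)].mean() for _ in range(n_boot)]
        )
        sem = reps.std(ddof=1)
        rows.append((label, x.mean(), x.mean() - 2 * sem, x.mean() + 2 * sem, x.size))
    return pd.DataFrame(rows, columns=["group", "mean", "lo", "hi", "n"]).set_index("group")
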