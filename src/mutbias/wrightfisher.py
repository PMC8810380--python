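"""Forward Wright-Fisher simulation of mutation bias versus purifying
selection in a selfing plant population.

A diploid population of N individuals evolves for a fixed number of
discrete generations. Offspring are produced by selfing with probability
sigma, otherwise by random outcrossing; parents are drawn in proportion
to viability. Each transmitted gamete receives a Poisson number of new
mutations with a per-bp rate that is ``u`` in intergenic space and
``u * gene_body_scale`` inside gene bodies; a configurable fraction of
new mutations per region kind is deleterious with fitness 1 - h*s (het) /
1 - s (hom), multiplicative across loci. At most one crossover occurs per
gamete, with the configured per-genome probability and a uniform
breakpoint. The final-generation sample yields a haplotype matrix,
windowed S and Tajima's D, and a VCF.

Also provides the drift-barrier calculator for the minimum sequence
length L over which a mutation-rate modifier is selectable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mutbias.genome import GeneModel, GenicFeature, GenomeAnnotation
from mutbias.popgen import windowed_scan


@dataclass(frozen=True)
class GenomeLayout:
    """Gene/intergenic partition of a simulated chromosome."""

    length: int
    genes: tuple[tuple[int, int], ...]  # sorted, disjoint [start, end)

    def __post_init__(self):
        last = 0
        for s, e in self.genes:
            if s < last or e <= s or e > self.length:
                raise ValueError("gene intervals must be sorted, disjoint, in range")
            last = e

    @classmethod
    def regular(
        cls, n_genes: int = 100, gene_length: int = 2000, intergenic: int = 3000
    ) -> "GenomeLayout":
        """n genes of fixed length separated (and flanked) by fixed
        intergenic spacers — the default simulated genome."""
        genes = []
        pos = intergenic
        for _ in range(n_genes):
            genes.append((pos, pos + gene_length))
            pos += gene_length + intergenic
        return cls(pos, tuple(genes))

    @classmethod
    def from_annotation(cls, annotation: GenomeAnnotation, chrom: str) -> "GenomeLayout":
        genes = sorted((g.start, g.end) for g in annotation.genes_on(chrom))
        merged: list[tuple[int, int]] = []
        for s, e in genes:
            if merged and s < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return cls(annotation.chrom_lengths[chrom], tuple(merged))

    @property
    def genic_length(self) -> int:
        return sum(e - s for s, e in self.genes)

    @property
    def intergenic_intervals(self) -> tuple[tuple[int, int], ...]:
        out = []
        last = 0
        for s, e in self.genes:
            if s > last:
                out.append((last, s))
            last = e
        if last < self.length:
            out.append((last, self.length))
        return tuple(out)

    def annotation(self, chrom: str = "sim") -> GenomeAnnotation:
        """Single-CDS plus-strand gene models over the layout (for
        metagene profiling of simulation output)."""
        genes = [
            GeneModel(
                f"simg{i + 1:04d}", chrom, "+", s, e, [GenicFeature("cds", s, e, 1)]
            )
            for i, (s, e) in enumerate(self.genes)
        ]
        return GenomeAnnotation([(chrom, self.length)], genes)

    def gene_body_mask_for_windows(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """True where the window midpoint falls inside a gene body."""
        mids = (np.asarray(starts) + np.asarray(ends)) // 2
        gs = np.array([s for s, _ in self.genes])
        ge = np.array([e for _, e in self.genes])
        idx = np.searchsorted(gs, mids, side="right") - 1
        ok = idx >= 0
        out = np.zeros(mids.shape, bool)
        out[ok] = mids[ok] < ge[idx[ok]]
        return out


@dataclass
class WrightFisherParams:
    """Simulation parameters (defaults follow the full-scale design:
    N = 1,000 diploids, 10,000 generations, selfing 0.98, baseline
    u = 3e-7 per bp per generation chosen to preserve the A. thaliana
    population mutation rate theta at the reduced N)."""

    N: int = 1000
    generations: int = 10_000
    selfing: float = 0.98
    u: float = 3e-7
    recombination: float = 1e-4
    gene_body_scale: float = 1.0
    del_fraction_genic: float = 0.0
    del_fraction_intergenic: float = 0.0
    s_del: float = 0.01
    h: float = 0.5
    layout: GenomeLayout = field(default_factory=GenomeLayout.regular)
    sample_haplotypes: int = 100
    window: int = 100
    purge_interval: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.selfing <= 1:
            raise ValueError("selfing rate must lie in [0,1]")
        if self.gene_body_scale <= 0:
            raise ValueError("gene_body_scale must be > 0")
        for f in (self.del_fraction_genic, self.del_fraction_intergenic):
            if not 0 <= f <= 1:
                raise ValueError("deleterious fractions must lie in [0,1]")
        if self.u < 0 or self.recombination < 0:
            raise ValueError("rates must be non-negative")
        if self.sample_haplotypes > 2 * self.N:
            raise ValueError("cannot sample more haplotypes than the population holds")

    @property
    def inbreeding_coefficient(self) -> float:
        """Equilibrium F = sigma / (2 - sigma)."""
        return self.selfing / (2 - self.selfing)

    @property
    def effective_size(self) -> float:
        """Selfing-adjusted Ne ~ N / (1 + F)."""
        return self.N / (1 + self.inbreeding_coefficient)


class ExtinctionError(RuntimeError):
    def __init__(self, generation: int):
        super().__init__(f"population fitness collapsed to zero at generation {generation}")
        self.generation = generation


@dataclass
class WrightFisherResult:
    """Final-generation sample and summaries of one simulation run."""

    params: WrightFisherParams
    positions: np.ndarray  # segregating positions in the sample, sorted
    haplotypes: np.ndarray  # (n_sites, n_haplotypes) 0/1; columns paired per individual
    windows: pd.DataFrame  # chrom/start/end/n/S/pi/D
    mutation_counts: dict[str, int]  # realized new-mutation counts by region kind
    n_fixed_purged: int
    seed: int

    @property
    def n_segregating(self) -> int:
        return int(self.positions.size)

    def mean_individual_heterozygosity(self) -> float:
        """Mean per-individual fraction of sampled sites at which the two
        haplotypes differ, divided by genome length (per-bp)."""
        H = self.haplotypes
        n_ind = H.shape[1] // 2
        if H.size == 0:
            return 0.0
        diffs = np.abs(H[:, 0 : 2 * n_ind : 2] - H[:, 1 : 2 * n_ind : 2]).sum(axis=0)
        return float(diffs.mean() / self.params.layout.length)

    def _region_window_means(self, col: str) -> tuple[float, float]:
        w = self.windows
        mask = self.params.layout.gene_body_mask_for_windows(
            w["start"].to_numpy(), w["end"].to_numpy()
        )
        vals = w[col].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gb = float(np.nanmean(vals[mask])) if mask.any() else float("nan")
            ig = float(np.nanmean(vals[~mask])) if (~mask).any() else float("nan")
        return gb, ig

    def gene_body_mean_D(self) -> float:
        return self._region_window_means("D")[0]

    def intergenic_mean_D(self) -> float:
        return self._region_window_means("D")[1]

    def gene_body_mean_S(self) -> float:
        return self._region_window_means("S")[0]

    def intergenic_mean_S(self) -> float:
        return self._region_window_means("S")[1]

    def to_vcf(self, path: str, chrom: str = "sim") -> None:
        """Write the sampled haplotypes as phased diploid genotypes."""
        n_ind = self.haplotypes.shape[1] // 2
        samples = [f"ind{i + 1:03d}" for i in range(n_ind)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={self.params.layout.length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for k, pos in enumerate(self.positions):
                gts = [
                    f"{self.haplotypes[k, 2 * i]}|{self.haplotypes[k, 2 * i + 1]}"
                    for i in range(n_ind)
                ]
                fh.write(f"{chrom}\t{pos + 1}\t.\tA\tT\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def simulate(params: WrightFisherParams, rng: np.random.Generator | None = None) -> WrightFisherResult:
    """Run one forward simulation; deterministic under (params, seed)."""
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    layout = params.layout
    N = params.N

    gene_starts = np.array([s for s, _ in layout.genes], dtype=np.int64)
    gene_lens = np.array([e - s for s, e in layout.genes], dtype=np.int64)
    gene_cum = np.concatenate([[0], np.cumsum(gene_lens)])
    Lg = int(gene_cum[-1])
    ig = layout.intergenic_intervals
    ig_starts = np.array([s for s, _ in ig], dtype=np.int64)
    ig_lens = np.array([e - s for s, e in ig], dtype=np.int64)
    ig_cum = np.concatenate([[0], np.cumsum(ig_lens)])
    Li = int(ig_cum[-1])

    w_gen = params.u * params.gene_body_scale * Lg
    w_int = params.u * Li
    lam = w_gen + w_int
    p_genic = w_gen / lam if lam > 0 else 0.0

    mut_pos: list[int] = []
    mut_del: list[bool] = []
    counts = {"gene_body": 0, "intergenic": 0}

    empty: frozenset = frozenset()
    hapsA = [(empty, empty)] * N  # (all mutations, deleterious subset)
    hapsB = [(empty, empty)] * N
    fitness = np.ones(N)
    any_selection = (
        params.s_del > 0
        and (params.del_fraction_genic > 0 or params.del_fraction_intergenic > 0)
    )
    s, h = params.s_del, params.h
    n_fixed_purged = 0

    def new_mutations(k: int) -> tuple[list[int], list[int]]:
        ids, dels = [], []
        for _ in range(k):
            if rng.random() < p_genic:
                off = int(rng.integers(Lg))
                gi = np.searchsorted(gene_cum, off, side="right") - 1
                pos = int(gene_starts[gi] + off - gene_cum[gi])
                is_del = rng.random() < params.del_fraction_genic
                counts["gene_body"] += 1
            else:
                off = int(rng.integers(Li))
                ii = np.searchsorted(ig_cum, off, side="right") - 1
                pos = int(ig_starts[ii] + off - ig_cum[ii])
                is_del = rng.random() < params.del_fraction_intergenic
                counts["intergenic"] += 1
            mid = len(mut_pos)
            mut_pos.append(pos)
            mut_del.append(is_del)
            ids.append(mid)
            if is_del:
                dels.append(mid)
        return ids, dels

    for gen in range(params.generations):
        if any_selection:
            total_w = fitness.sum()
            if total_w <= 0:
                raise ExtinctionError(gen)
            probs = fitness / total_w
            par1 = rng.choice(N, size=N, p=probs)
            par2 = rng.choice(N, size=N, p=probs)
        else:
            par1 = rng.integers(0, N, size=N)
            par2 = rng.integers(0, N, size=N)
        selfed = rng.random(N) < params.selfing
        par2 = np.where(selfed, par1, par2)

        n_mut = rng.poisson(lam, size=2 * N)
        recomb = rng.random(2 * N) < params.recombination
        which = rng.integers(0, 2, size=2 * N)

        newA: list[tuple[frozenset, frozenset]] = [None] * N  # type: ignore
        newB: list[tuple[frozenset, frozenset]] = [None] * N  # type: ignore
        new_fit = np.ones(N)
        for i in range(N):
            child = []
            for side, par in ((0, par1[i]), (1, par2[i])):
                gi2 = 2 * i + side
                A_all, A_del = hapsA[par]
                B_all, B_del = hapsB[par]
                if recomb[gi2]:
                    bp = int(rng.integers(layout.length))
                    left, right = (A_all, B_all) if which[gi2] == 0 else (B_all, A_all)
                    hap_all = frozenset(
                        m for m in left if mut_pos[m] < bp
                    ) | frozenset(m for m in right if mut_pos[m] >= bp)
                    hap_del = frozenset(m for m in hap_all if mut_del[m])
                else:
                    hap_all, hap_del = (A_all, A_del) if which[gi2] == 0 else (B_all, B_del)
                k = n_mut[gi2]
                if k:
                    ids, dels = new_mutations(int(k))
                    hap_all = hap_all | frozenset(ids)
                    if dels:
                        hap_del = hap_del | frozenset(dels)
                child.append((hap_all, hap_del))
            newA[i], newB[i] = child[0], child[1]
            if any_selection:
                dA, dB = child[0][1], child[1][1]
                if dA or dB:
                    nhom = len(dA & dB)
                    nhet = len(dA) + len(dB) - 2 * nhom
                    new_fit[i] = (1 - s) ** nhom * (1 - h * s) ** nhet
        hapsA, hapsB, fitness = newA, newB, new_fit

        if params.purge_interval and (gen + 1) % params.purge_interval == 0:
            fixed = None
            for hap, _ in itertools.chain(hapsA, hapsB):
                fixed = set(hap) if fixed is None else (fixed & hap)
                if not fixed:
                    break
            if fixed:
                n_fixed_purged += len(fixed)
                memo: dict[int, tuple[frozenset, frozenset]] = {}

                def strip(pair):
                    key = id(pair[0])
                    if key not in memo:
                        memo[key] = (pair[0] - fixed, pair[1] - fixed)
                    return memo[key]

                hapsA = [strip(p) for p in hapsA]
                hapsB = [strip(p) for p in hapsB]

    # --- final sample ------------------------------------------------------
    n_ind = params.sample_haplotypes // 2
    chosen = rng.choice(N, size=n_ind, replace=False)
    sample = []
    for i in chosen:
        sample.append(hapsA[i][0])
        sample.append(hapsB[i][0])
    n_hap = len(sample)
    from collections import Counter

    occurrence = Counter()
    for hap in sample:
        occurrence.update(hap)
    seg_ids = sorted(
        (m for m, c in occurrence.items() if 0 < c < n_hap), key=lambda m: mut_pos[m]
    )
    positions = np.array([mut_pos[m] for m in seg_ids], dtype=np.int64)
    col = {m: k for k, m in enumerate(seg_ids)}
    H = np.zeros((len(seg_ids), n_hap), dtype=np.int8)
    for j, hap in enumerate(sample):
        for m in hap:
            k = col.get(m)
            if k is not None:
                H[k, j] = 1
    windows = windowed_scan(
        positions, H, layout.length, window=params.window, chrom="sim", ploidy=1
    )
    return WrightFisherResult(
        params, positions, H, windows, dict(counts), n_fixed_purged, params.seed
    )


# ---------------------------------------------------------------------------
# Parameter grid
# ---------------------------------------------------------------------------

def grid_run(
    base: WrightFisherParams,
    scales: tuple[float, ...] = (0.2, 0.5, 1.0),
    del_fractions: tuple[float, ...] = (0.0, 0.1, 0.3),
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every (gene-body scale, genic deleterious fraction)
    combination ``reps`` times with seeds derived deterministically from
    ``seed``. Returns one row per run with region-mean S and D."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    combos = list(itertools.product(scales, del_fractions))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(combos) * reps)
    rows = []
    k = 0
    for scale, fdel in combos:
        for rep in range(reps):
            params = replace(
                base, gene_body_scale=scale, del_fraction_genic=fdel
            )
            res = simulate(params, rng=np.random.default_rng(children[k]))
            k += 1
            rows.append(
                {
                    "scale": scale,
                    "del_fraction": fdel,
                    "rep": rep,
                    "S_gene_body": res.gene_body_mean_S(),
                    "S_intergenic": res.intergenic_mean_S(),
                    "D_gene_body": res.gene_body_mean_D(),
                    "D_intergenic": res.intergenic_mean_D(),
                    "n_segregating": res.n_segregating,
                }
            )
    return pd.DataFrame(rows)


def sign_contrast(
    base: WrightFisherParams,
    reps: int = 20,
    seed: int = 0,
    hypo_scale: float = 0.2,
    selection_fraction: float = 0.3,
) -> pd.DataFrame:
    """Hypomutation-vs-selection direction test on gene-body Tajima's D.

    Per replicate ensemble, three runs are simulated: a neutral uniform
    run (scale 1, no deleterious mutations), a gene-body hypomutation run
    (scale ``hypo_scale``, neutral) and a purifying-selection run (scale 1,
    genic deleterious fraction ``selection_fraction``). The expected
    directions are: hypomutation raises gene-body D relative to the
    neutral run (fewer young alleles), purifying selection lowers it
    (excess rare alleles). Returns one row per ensemble with the three
    gene-body mean window D values and boolean direction outcomes.
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(3 * reps))
    rows = []
    for rep in range(reps):
        rn = simulate(
            replace(base, gene_body_scale=1.0, del_fraction_genic=0.0),
            rng=np.random.default_rng(next(children)),
        )
        rh = simulate(
            replace(base, gene_body_scale=hypo_scale, del_fraction_genic=0.0),
            rng=np.random.default_rng(next(children)),
        )
        rs = simulate(
            replace(base, gene_body_scale=1.0, del_fraction_genic=selection_fraction),
            rng=np.random.default_rng(next(children)),
        )
        dn, dh, ds = (
            rn.gene_body_mean_D(),
            rh.gene_body_mean_D(),
            rs.gene_body_mean_D(),
        )
        rows.append(
            {
                "rep": rep,
                "D_gb_neutral": dn,
                "D_gb_hypomutation": dh,
                "D_gb_selection": ds,
                "hypo_up": bool(dh > dn),
                "selection_down": bool(ds < dn),
            }
        )
    return pd.DataFrame(rows)


def desk_scale_params(scaling: float = 5.0) -> WrightFisherParams:
    """Rescaled simulation design for desk-scale runs.

    Standard forward-simulation rescaling by factor Q: N and generation
    count divided by Q; per-generation mutation rate, recombination
    probability and selection coefficient multiplied by Q, preserving the
    population-scaled parameters (theta = 4Nu, population recombination
    input and N*s). With Q = 5 the full design (N = 1,000, 10,000
    generations, u = 3e-7, r = 1e-4) becomes N = 200, 2,000 generations,
    u = 1.5e-6, r = 5e-4 on a 100-kb genome of 20 genes.
    """
    q = scaling
    return WrightFisherParams(
        N=int(1000 / q),
        generations=int(10_000 / q),
        u=3e-7 * q,
        recombination=1e-4 * q,
        selfing=0.98,
        s_del=0.01 * q,
        h=0.5,
        layout=GenomeLayout.regular(n_genes=int(100 / q), gene_length=2000, intergenic=3000),
        sample_haplotypes=100,
    )


def compare_to_empirical(
    sim_profiles: dict, empirical, quantity: str = "D"
) -> pd.DataFrame:
    """Pearson r between each combination's simulated profile and an
    empirical profile (constant empirical profile -> NaN marker).

    ``sim_profiles`` maps a combination key to a ProfileCurve; ``empirical``
    is a ProfileCurve on the same offsets.
    """
    from mutbias.profiles import compare_curves

    rows = []
    for key, curve in sim_profiles.items():
        rep = compare_curves(empirical, curve)
        rows.append({"combo": key, "quantity": quantity, "r": rep.r})
    df = pd.DataFrame(rows)
    finite = df.dropna(subset=["r"])
    df.attrs["best_combo"] = (
        finite.loc[finite["r"].idxmax(), "combo"] if len(finite) else None
    )
    return df


# ---------------------------------------------------------------------------
# Drift-barrier theory for mutation-rate modifiers
# ---------------------------------------------------------------------------

@dataclass
class ModifierTheoryParams:
    """Parameters of the modifier-evolvability (drift-barrier) calculation.

    A modifier reduces the deleterious mutation rate by fraction ``r``
    over ``L`` bp; its selective advantage is s_mod = r * u_del * L where
    u_del = u * f_del is the per-bp deleterious mutation rate. It is
    selectable when s_mod exceeds the drift barrier 1/(2 Ne).
    """

    r: float = 0.30
    u: float = 1e-9
    f_del: float = 0.5
    ne: float = 3e5

    def __post_init__(self):
        if not 0 < self.r <= 1:
            raise ValueError("r must lie in (0, 1]")
        if min(self.u, self.f_del, self.ne) <= 0:
            raise ValueError("u, f_del and Ne must be positive")

    @property
    def u_del(self) -> float:
        return self.u * self.f_del


def l_segment_min(params: ModifierTheoryParams, advantage=None) -> float:
    """Minimum sequence length (bp) over which a hypomutation modifier is
    selectable: solves s_mod(L) = 1/(2 Ne).

    With the default linear advantage s_mod = r*u_del*L this is
    L_min = 1 / (2 Ne r u_del); a custom monotone ``advantage(L)``
    callable is solved numerically.
    """
    barrier = 1.0 / (2.0 * params.ne)
    if advantage is None:
        return barrier / (params.r * params.u_del)
    from scipy.optimize import brentq

    hi = 1.0
    while advantage(hi) < barrier:
        hi *= 10
        if hi > 1e15:
            raise ValueError("advantage never exceeds the drift barrier")
    return float(brentq(lambda L: advantage(L) - barrier, 0.0, hi))
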