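# Methods

`mutbias` implements an analysis chain for asking whether de novo mutations
in a gene-dense plant genome fall uniformly with respect to gene structure
and chromatin state, and what the population-genetic consequences of any
bias are. This note documents the models, the choices behind them, and what
the synthetic-data tests do and do not establish.

## Genic-feature decomposition

Gene models are reduced to one canonical transcript per gene (the longest
mRNA) and decomposed into `upstream`, `utr5`, `cds` (ranked 1..k in
transcription order), `intron` (ranked), `utr3` and `downstream` features.
All coordinates are 0-based half-open internally; GFF3 and VCF are converted
at the boundary, which confines off-by-one risk to two code paths.

Upstream/downstream flanks are fixed 3,000-bp windows (configurable), not
truncated at neighbouring genes: metagene figures deliberately do not
distinguish genes or intergenic spaces shorter than the flank, and the
decomposition makes the same choice so region-level counts and profile
curves agree. A base may therefore belong to several genes' regions;
region-level counting makes any double counting explicit (the sum of region
counts can exceed the number of mutations) rather than hiding an
arbitration rule.

## Curation of mutation-accumulation call sets

Three rules: QD > 30 and DP > 3 (strict inequalities; a missing value
fails — conservative, because the pipeline exists to produce a
high-confidence set); removal of variants with any base of mappability
below 1.0 within ±100 bp (inclusive window, 201 bases); and origin
classification within founder groups — homozygous-alternative in exactly
one line is germline, heterozygous in exactly one line is somatic, and a
variant seen in more lines than allowed (default 1) is removed as standing
variation or artefact. The filters commute and are idempotent, so
pipeline order cannot change results; each removal is attributed to
exactly one rule in the log.

## Region features and the mutation-rate model

The design matrix has one row per genic-feature instance: length, GC
fraction, methylated-cytosine counts per bp by context (CG/CHG/CHH),
region means of unit-scaled (genome-wide maximum) signal tracks, and
gene-level expression broadcast to the gene's regions. Genes lacking
expression are dropped from fitting by default, with mean imputation
available behind a flag.

The model is ordinary least squares on the *untransformed* per-bp rate
(identity link, normality assumed). This is deliberately plain: the
response is a small count over a known length and the model's job is
prediction, not per-coefficient causal inference. A Poisson variant (log
link, length offset) is provided for sensitivity checks only.

Model search is bidirectional stepwise AIC starting from the full model.
Internally the search ranks candidate models by the Gaussian profile AIC
`n·log(RSS/n) + 2·edf` (the `extractAIC` convention, which orders models
identically to the full-likelihood AIC); ties within 1e-9 go to the
smaller model, and the RSS is floored at the numerical precision of an
exact fit so that a noiseless response selects the minimal true model
rather than ranking round-off. The search is deterministic given the
table and candidate order.

Collinearity is handled separately: iterative removal of the predictor
with the **largest** variance inflation factor until all remaining VIFs
fall below 3, refitting each round. (The one-pass removal of *low*-VIF
predictors is available as `direction="literal"` for comparison; it
discards the independent predictors and is not the default because the
purpose of the step is to drop over-correlated ones.)

Prediction produces the mutation probability score: predicted SNV +
indel rate per bp, per region; gene scores are length-weighted means;
negative predictions are retained but flagged (an identity-link model
admits them). Deciles are equal-sized with ties broken by stable gene-id
order.

## Random-mutation null models

The substitution spectrum is specified over the six strand-symmetrized
classes (C>T, C>A, C>G, T>A, T>C, T>G). The default generator spectrum is
C>T-dominant (0.45), with the remaining mass spread over transversions and
T>C transitions — a realistic shape for a plant germline in which
methylated-cytosine deamination dominates; it is a package default, not a
fitted quantity, and `MutationSpectrum.from_mutations` computes empirical
spectra.

Coding effects are classified against the standard genetic code on the
spliced CDS in transcription orientation; stop-gained changes are counted
with non-synonymous changes when forming NS/S ratios. A `CodingIndex`
pre-classifies every CDS base × alternative allele once, so the NS/S null
(uniform placement of n mutations, spectrum-conditioned alleles, repeated
`reps` times) runs as array lookups. The expected synonymous *fraction* is
computed deterministically by enumeration over all CDS positions and
alternatives weighted by the spectrum, replacing sampling noise where
sampling adds nothing; the expected synonymous *count* then multiplies the
per-replicate number of coding hits by that fraction.

Selection thinning removes each coding mutation independently with
probability s (a dominant-lethal caricature of strong purifying
selection, with s up to 0.3 as the extreme positive control); it exists to
show what selection on de novo mutations *would* look like in metagene
profiles — a depletion confined to CDS with flat introns/UTRs — so that
observed gene-body depletion spanning introns and UTRs cannot be
attributed to it.

Ratio comparisons use the 2×2 chi-squared test without continuity
correction (all intended uses have large counts).

## Site-frequency statistics

Windowed scans tile each chromosome with 100-bp windows (configurable).
Per-site π comes from allele counts, `2k(n−k)/(n(n−1))`, with n the
*called* alleles at that site (vcftools convention; missing genotypes
shrink the denominator rather than dropping the site). Tajima's D uses
the standard constants; within a window the constants take the mean
called-allele count over segregating sites (rounded), which is exact
whenever data are complete. Windows with S = 0 carry an undefined marker
and are skipped when averaging (zero-fill is not the default; the choice
matters and is exposed to the caller by operating on the returned frame).

MK α = 1 − (Ds·Pn)/(Dn·Ps) with undefined markers when Dn or Ps is 0;
Pn/Ps/Dn/Ds arrive as counts (ortholog alignment is out of scope).
Loss-of-function is premature stop, or frameshift disrupting ≥10% of the
CDS (fraction of CDS bases at or downstream of the lesion, boundary
inclusive). Polymorphism residuals are OLS residuals of per-gene
polymorphism on predicted score, divided by their standard deviation;
numerically exact fits return zeros rather than normalized round-off.

## Metagene profiles

Offsets are transcription-oriented (negative = upstream), so minus-strand
genes are flipped. Genes shorter than the flank contribute gene-body bins
only up to their length; bins reaching past a chromosome end are masked
per gene. Event inputs become per-bp rates before averaging; windowed
statistics are assigned to window midpoints with undefined values skipped.
The confidence band is ±2 s.e.m. where the s.e.m. is the standard
deviation of 100 bootstrap replicate means over genes. Curve agreement is
Pearson r plus the R² from regressing one curve on the other.

## Forward Wright–Fisher simulation

Discrete generations; N diploids; offspring by selfing with probability
σ (default 0.98) else random outcrossing; viability-proportional parent
sampling; at most one crossover per gamete with the configured per-genome
probability (literal reading of a "per genome per generation"
recombination probability) at a uniform breakpoint; Poisson mutation per
gamete with per-bp rate u intergenic and u × scale in gene bodies;
deleterious fractions per region kind, fitness 1−hs (het) and 1−s (hom)
multiplied across loci. Haplotypes are stored as shared immutable
mutation-id sets, copied only on mutation or crossover, with fixed
mutations purged periodically — this makes desk-scale runs take seconds.

The full-scale design is N = 1,000 for 10,000 generations on 100 genes of
2 kb separated by 3 kb, u = 3×10⁻⁷ per bp per generation (the population
mutation rate of *A. thaliana*, N_e ≈ 3×10⁵ at u ≈ 1×10⁻⁹, preserved at
the reduced simulated N), recombination 1×10⁻⁴ per genome. The selection
coefficient of deleterious mutations is not pinned by any external
estimate; the package default is s = 0.01, h = 0.5, and s is a parameter
the user should vary.

Desk-scale runs use standard forward-simulation rescaling by Q = 5:
N = 200, 2,000 generations, u = 1.5×10⁻⁶, r = 5×10⁻⁴, s = 0.05, 20 genes
(100-kb genome), preserving 4Nu, the population recombination input and
N·s. `desk_scale_params()` constructs exactly this design and the test
suite and acceptance script use it; the problem sizes were chosen once
from the rescaling rule.

`sign_contrast` runs the three-way direction experiment per replicate
ensemble: neutral uniform, gene-body hypomutation (scale 0.2), and
purifying selection (genic deleterious fraction 0.3), comparing mean
gene-body window D with the neutral run. Theory predicts hypomutation
raises D (fewer young alleles) and purifying selection lowers it (excess
rare alleles).

### Known limitation: per-ensemble D directions at desk scale

The direction test is an ensemble-mean property, not a per-run one, and
the validation suite documents this honestly rather than weakening the
assertion. Two separate facts matter.

First, the purifying-selection direction *is* reproduced in the ensemble
mean: over 25 desk-scale replicates the pooled gene-body D under a 30%
genic deleterious fraction sits ≈ 0.33 below its intergenic baseline
(roughly 5 standard errors), while neutral runs show no offset. But a
single run's gene-body mean window D varies between runs by several
times that effect (each run is one genealogy), so per-ensemble
comparisons against an independently simulated neutral run succeed in
only ~65–75% of ensembles, not ≥90%.

Second, the hypomutation direction shows no per-run signal at all at
σ = 0.98, at desk scale or near full scale. The reason is structural:
crossovers in near-homozygous selfers are mostly silent, so all windows
of a run share essentially one genealogy. Conditional on that genealogy,
placing fewer mutations in gene bodies subsamples the same branch-length
distribution — the SFS *shape* is rate-invariant — so the mean
per-window D carries no rate effect within a run; what remains is a
small-S discreteness bias in the opposite direction. The theoretical
effect (lower θ → less negative D through S-dependent normalization and
the conditioning of observed windows on S > 0) emerges only across many
independent genealogies — hundreds of replicates, beyond a desk budget.

The simulator itself is validated independently against Watterson's
E[S], the selfing–heterozygosity relation and the programmed gene-body
mutation-count ratio.

## Drift-barrier modifier length

A modifier reducing the deleterious mutation rate by fraction r over L bp
gains s_mod = r·u_del·L per generation (u_del = u·f_del). It is selectable
where s_mod exceeds the drift barrier 1/(2N_e), giving
L_min = 1/(2·N_e·r·u_del). The linear advantage model is a documented
choice; `l_segment_min` accepts any monotone advantage function and solves
numerically.

## What the synthetic data do and do not show

The generator produces gene-dense genomes with realistic region structure
and composition, tracks with programmed region/class means plus iid
Gaussian noise, and mutations placed by an explicit linear rate law with
region multipliers. Passing tests therefore demonstrate that the pipeline
*recovers programmed structure* — coefficients, rate ratios, class
contrasts, null ratios — under the stated noise. They do not demonstrate
that real epigenomic marks predict real mutation rates: real tracks are
spatially autocorrelated, cross-correlated and confounded in ways the
generator deliberately omits (no transposon/repeat structure, no codon
bias beyond GC targets, iid noise). Headline effect sizes from real data
(percent reductions in gene bodies or essential genes, r ≈ 0.96 curve
agreement) live on datasets requiring raw-read reanalysis and are not
reproduced here.

## Problem sizes used in validation

Tajima oracle: 100 matrices of 50 samples × 100 sites. Model recovery:
5,000 regions, 2×10⁴ mutations, 3 signal + 10 noise predictors, 100
seeds. Profile ratio: 500 genes, 10⁴ events. NS/S null: ≤10-kb genome,
1,000 replicates of 10⁴ mutations. Thinning: ~10⁴ coding events. Forward
simulation: the Q = 5 desk design above, 20 replicate ensembles × 3
conditions.
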