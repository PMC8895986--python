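# Methods

`kelpsim` simulates recurrent genomic selection in a haplodiplontic crop
such as sugar kelp (*Saccharina latissima*), where the farm-evaluated plant
is a diploid sporophyte (SP) and the selection candidates propagated in the
laboratory are haploid, sexed gametophytes (GP).  The package exists to rank
four practical obstacles to genetic gain — breeding-cycle length, plot
capacity, the ability to select reproductively competent sporophytes, and
gametophyte supply per sporophyte — by simulating a 10-year breeding program
under a 2^6 factorial of scheme settings and summarizing genetic mean,
genetic variance and genomic-prediction accuracy.

## Genome and meiosis

Genomes are 31 chromosomes of 1 Morgan carrying 500 biallelic segregating
sites each, of which 100 per chromosome act as additive QTL and the rest are
available as genotyping markers (QTL and markers are disjoint; the GS model
never observes QTL directly, the conservative standard choice).  Site
positions are uniform per chromosome.

Recombination uses the stationary gamma renewal model of chiasma formation:
chiasma interarrival distances on the four-strand bundle are
Gamma(ν, scale = 1/(2ν)) so the chiasma intensity is 2 per Morgan, the first
chiasma is drawn from the equilibrium forward-recurrence law (sampled
exactly as `T·U` with `T ~ Gamma(ν+1)`, `U ~ Uniform`), and each chiasma
involves a given chromatid with probability 1/2 (no chromatid
interference), leaving 1 crossover per Morgan on the gamete.  The default
interference shape ν = 2.63 makes the implied map function nearly
indistinguishable from Kosambi's r = tanh(2d)/2: because the thinning
randomizes parity whenever at least one chiasma falls in an interval, the
model's recombination fraction has the closed form r(d) = F_e(d)/2 with
F_e the equilibrium first-arrival CDF, and its deviation from Kosambi is
below 1e-3 for d ≤ 1 Morgan.  The test suite uses this closed form as an
independent oracle for the meiosis code.

For throughput, meioses are sampled as "recipes" (crossover positions and
per-chromosome starting phases) that are independent of any site set; a
recipe can be materialized on the full map or on a site subset with
identical results.  The cycle engine materializes selection candidates only
at marker+QTL columns and reconstructs full genomes solely for the
gametophytes that are actually crossed.  Both paths consume the random
stream identically, so restricted and unrestricted runs of the same seed
coincide exactly (tested).

## Trait model

The trait is purely additive (no dominance, epistasis or G×E — consistent
with the absence of evidence for heterosis or inbreeding depression in this
crop's early breeding data).  QTL effects are drawn iid standard normal and
affinely rescaled so the founder cohort has genetic mean 0 and variance
exactly 1; heritability enters only through the plot error variance
σ²E = σ²A(1−h²)/h², i.e. 4 and 1 for h² = 0.2 and 0.5.  Gametophyte genetic
values are reported on the doubled-haploid scale (twice the haploid QTL
dosage), i.e. the value of the homozygous sporophyte the gametophyte would
found, so GP-stage and SP-stage means are directly comparable; within-sex
truncation selection is invariant to this scale choice.

## Founder population

Founders are 1,000 sporophytes whose background LD is governed by an
effective population size Ne ∈ {60, 600}.  They are generated by a neutral
forward-in-time burn-in: sites start at linkage equilibrium with minor
allele frequencies uniform on [0.05, 0.5]; a Wright–Fisher population of Ne
diploids random-mates (selfing allowed) for 100 generations; the population
is then expanded to 1,000 by one more round of random mating.  A
forward-time backend was preferred over a coalescent because the LD that
matters for the Sved average — moderate-to-loose linkage — equilibrates
within O(1/c) generations; the generator is pluggable and the acceptance
gate is agreement with Sved's expectation E[r²] ≈ 1/(1+4·Ne·c), checked at
c = 0.5 against the generated founders (within a factor-2 band: the formula
is approximate, alternative drift derivations differ by constants of order
one, and the genotype-based estimator carries a finite-sample inflation of
order 1/n).  More sites than needed are simulated (the oversampling factor
anticipates drift fixation via the heterozygosity retention exp(−g/2Ne))
and 500 sites per chromosome segregating at MAF ≥ 0.01 are retained.

`estimate_Ne` implements the printed inversion Ne = (1/E[r²] − 1)/(4c)
as-is.  Applied to an observed mean LD of 0.08 at c = 0.5 it returns 5.75;
the configured Ne values 60 and 600 are treated as simulation inputs, not
derived quantities.

## Genomic selection

The GS model is ridge-regression BLUP on centered marker dosages with an
intercept: `y = 1μ + Xu + e`, `u ~ N(0, σ²u I)`.  By default the shrinkage
ratio λ = σ²e/σ²u is re-estimated by REML at every cycle via a spectral
decomposition taken on whichever side of the marker/kernel duality is
smaller, with a bounded one-dimensional search over log λ.  The training
population accumulates every phenotyped cohort (founders, being
wild-collected rather than farm-evaluated, contribute none); sufficient
statistics (Gram matrix, cross-products) are maintained incrementally so
fixed-λ refits on the growing record base cost one Cholesky solve.  The
fixed-λ override `gs_lambda="auto"` uses λ = m·σ²E/σ²A, the value implied by
equally splitting the additive variance across m marker effects; it is the
default for the scaled-down factorial, where REML at every cycle would
dominate runtime without changing truncation rankings materially.
Large-panel solves use single precision; this perturbs GEBVs by parts in
1e-7, far below the between-candidate spread that truncation selection acts
on.  Prediction accuracy is the Pearson correlation of GEBVs with true
genetic values among the GP candidates.

## Breeding cycle and calendar

Year 1: each of the 1,000 founders contributes 2 gametophytes (no selection
pressure), sexes assigned F/M independently with probability 1/2; a random
NumCross/2 of each sex are crossed.  A cohort crossed in year t is
phenotyped in year t+1, and the routine scheme starts in year 2.  Each
cycle: the newly evaluated cohort joins the training set; 10% of its
NumCross plots are selected (randomly or by phenotype); each selected SP
releases nGP gametophytes by meiosis; the GS model is refit and all
candidates are GEBV-ranked; the top NumCross/2 per sex are kept; two
independent random bijections between the female and male lists make
NumCross crosses, so every selected gametophyte is used exactly twice
(selfing-equivalent pairs allowed; if the two bijections coincide on any
pair the second is redrawn once and then accepted — the event is negligible
at scheme scale).  Every evaluation year through the 10-year horizon runs
this gametophyte stage, including the final one: the year-10 harvest still
joins the training set (so the 1-year scheme ends with NumCross·9 training
records) and still releases and ranks gametophytes, but crossing happens
only when the resulting cohort can be evaluated within the horizon.  The
1-year cycle therefore logs gametophyte cohorts in years 1–10 with 8
crossing rounds, the 2-year cycle in years 1, 2, 4, 6, 8 and 10 with 4;
cycles are non-overlapping.  Sex
assignment is unconstrained binomial; at the reference parameters a sex
shortfall is vanishingly unlikely and raises an explicit error rather than
being silently redrawn.  All truncation ties break by id order for seeded
reproducibility.

Per-year metrics (genetic mean, total genetic variance, GS accuracy) are
computed on the GP candidate cohort before GP selection — the accuracy needs
the full candidate set — and carried forward through years without a new GP
cohort.  The 10-year gain scalar is the year-10 minus year-1 GP-cohort
genetic mean — total progress from the unselected founder gametophyte
stage, whose mean is ~0 by trait scaling; anchoring at the measured year-1
value rather than literal zero pairs out founder sampling noise.

## Factorial experiment and summaries

The design fully crosses nGP (24/96) × h² (0.2/0.5) × Ne (60/600) ×
NumCross (400/1,000) × SelectSP (random/pheno) × CycleTime (2/1 years):
64 settings, default 20 replicates (1,280 runs).  Founder populations and
traits are cached per (Ne, replicate) and shared by the 32 settings at that
Ne; with one QTL-effect vector per cache entry the factor contrasts are
paired on common founders, which sharpens the percent-change estimates
without breaking the sweep's seed discipline (the sweep remains a pure
function of design and base seed, independent of execution order, and
checkpointable per run).

Percent gain changes per intervention are
100·(mean gain at intervention − mean gain at reference)/reference, averaged
across all 32 complementary factor combinations (including Ne and h²).  The
all-interventions fold change is computed per (Ne, h²) slice and averaged.
ANOVA of per-replicate gain within an (Ne, h²) slice fits the 4 scheme main
effects plus all 6 pairwise interactions by OLS; the slice must be balanced,
in which case all classical sums-of-squares types coincide (verified against
an explicit ±1-contrast least-squares oracle).  No multiple-testing
correction is applied (raw P-values are reported).

## Problem sizes

The full-scale design (20 replicates, all 400 markers per chromosome, REML
each cycle) is CPU-feasible but slow; the package's reduced standard run —
used by `scripts/acceptance.py` and the acceptance tests — keeps every
structural parameter of the design (full genome, 1,000 founders, all 64
settings) and scales down only the Monte-Carlo effort: 5 replicates per
setting, GS markers downsampled to 50 per chromosome (1,550 genome-wide),
and the heuristic fixed shrinkage ratio.  Replicate-level standard errors
quantify the residual sampling noise of the percent-change estimates.

## What the generator does and does not emulate

The synthetic founders reproduce the stated founder structure: Ne-governed
background LD, a polygenic additive trait with unit genetic variance, and
the two heritability settings.  They do not model the real Gulf-of-Maine
population's substructure, marker ascertainment or missingness, mutation,
sex chromosomes, or non-additive gene action; passing tests therefore
demonstrate the internal consistency of the scheme comparison under the
stated assumptions, not the field performance of any particular breeding
population.  Because all four obstacle contrasts are relative (percent
changes between scheme variants under identical founders), their ranking is
expected to be robust to these simplifications — the comparison's central
premise — while absolute gains in trait units are not interpretable beyond
the simulation.

## Numerical choices and degenerate inputs

Zero phenotypic variance in training yields the null model (all effects 0,
flagged).  λ = ∞ is accepted and returns the null model, giving an exact
no-information control.  Monomorphic marker pairs are excluded from LD
summaries (undefined correlation).  Zero-variance inputs to accuracy or
empirical selection intensity return NaN with a warning.  Map positions may
coincide (such sites never recombine).  The REML search is bounded on
log λ ∈ [log 1e-8, log 1e10] with tolerance 1e-6.

## Known limitations

Non-overlapping cycles only; no gametophyte banking, multi-location
testing, G×E, mutation, or economic weighting of the interventions.  The
2-year scheme is interpreted as evaluating a new cohort every second year
(training size grows accordingly); the alternative with interleaved
phenotyping-only years is not modelled.
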