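"""Genome representation, meiosis with crossover interference, and additive traits.

The organism modelled here has a haplodiplontic life cycle: diploid
sporophytes undergo meiosis to release haploid gametophytes, and fusing a
female with a male gametophyte founds a new (genetically uniform) sporophyte.
Chromosomes are biallelic site vectors on a genetic map measured in Morgans.

Recombination follows the stationary gamma renewal model of chiasma
formation: chiasmata occur along the four-strand bundle as a renewal process
with gamma-distributed interarrival distances (shape ``nu`` controls
interference; ``nu = 1`` is the no-interference Poisson limit) at an
intensity of 2 chiasmata per Morgan, and each chiasma involves a given
chromatid with probability 1/2, so a gamete sees on average 1 crossover per
Morgan.  With ``nu`` near 2.6 the implied map function closely approximates
Kosambi's ``r = tanh(2d)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "GenomeParams",
    "GeneticMap",
    "TraitModel",
    "sample_crossovers",
    "crossover_counts",
    "meiosis",
    "meiosis_batch",
    "CrossoverRecipes",
    "sample_meiosis_recipes",
    "apply_meiosis_recipes",
    "cross",
    "genetic_value",
    "genetic_value_haploid",
    "genetic_value_diploid",
    "phenotype",
    "error_variance_for_h2",
    "write_vcf",
]

#: chiasma intensity on the four-strand bundle, events per Morgan
CHIASMA_RATE = 2.0


@dataclass(frozen=True)
class GenomeParams:
    """Genome architecture: chromosome count, sites, QTL and interference."""

    n_chromosomes: int = 31
    sites_per_chromosome: int = 500
    qtl_per_chromosome: int = 100
    chromosome_length: float = 1.0  # Morgans
    interference_shape: float = 2.63  # gamma shape nu

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.sites_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one site")
        if self.qtl_per_chromosome > self.sites_per_chromosome:
            raise ValueError("qtl_per_chromosome exceeds sites_per_chromosome")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be positive")


class GeneticMap:
    """Ordered site positions (Morgans) per chromosome.

    Positions must be non-decreasing within a chromosome and lie inside
    ``[0, length]``.  Sites at identical positions are permitted and never
    recombine.
    """

    def __init__(self, positions: list[np.ndarray], lengths: list[float] | np.ndarray):
        self.positions = [np.asarray(p, dtype=np.float64) for p in positions]
        self.lengths = np.asarray(lengths, dtype=np.float64)
        if len(self.positions) != len(self.lengths):
            raise ValueError("one length per chromosome required")
        for pos, length in zip(self.positions, self.lengths):
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
            if np.any(np.diff(pos) < 0):
                raise ValueError("site positions must be non-decreasing")
            if pos.size and (pos[0] < 0 or pos[-1] > length):
                raise ValueError("site positions must lie within [0, length]")
        self.n_chromosomes = len(self.positions)
        sizes = np.array([p.size for p in self.positions])
        self.chr_offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.n_sites = int(self.chr_offsets[-1])
        self.flat_positions = (
            np.concatenate(self.positions) if self.n_sites else np.empty(0)
        )
        self.chrom_of_site = np.repeat(
            np.arange(self.n_chromosomes, dtype=np.int64), sizes
        )

    @classmethod
    def random(cls, params: GenomeParams, rng: np.random.Generator) -> "GeneticMap":
        """Draw site positions uniformly per chromosome, then sort."""
        positions = [
            np.sort(rng.uniform(0.0, params.chromosome_length, params.sites_per_chromosome))
            for _ in range(params.n_chromosomes)
        ]
        return cls(positions, [params.chromosome_length] * params.n_chromosomes)

    def subset(self, flat_indices: np.ndarray) -> "GeneticMap":
        """Map restricted to a sorted subset of flat site indices."""
        flat_indices = np.asarray(flat_indices)
        positions = []
        for c in range(self.n_chromosomes):
            lo, hi = self.chr_offsets[c], self.chr_offsets[c + 1]
            sel = flat_indices[(flat_indices >= lo) & (flat_indices < hi)] - lo
            positions.append(self.positions[c][sel])
        return GeneticMap(positions, self.lengths)

    def to_frame(self):
        """Three-column table: chromosome, site index, position (Morgans)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chromosome": self.chrom_of_site + 1,
                "site": np.concatenate(
                    [np.arange(p.size) for p in self.positions]
                ),
                "position_morgans": self.flat_positions,
            }
        )


# ---------------------------------------------------------------------------
# Crossover sampling
# ---------------------------------------------------------------------------


def _stationary_first_event(
    shape: float, scale: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Draw the first chiasma position under the equilibrium renewal law.

    The stationary forward-recurrence density of a Gamma(shape, scale)
    renewal process is (1 - F(x)) / mean, which equals the law of T*U with
    T ~ Gamma(shape + 1, scale) and U ~ Uniform(0, 1).
    """
    return rng.gamma(shape + 1.0, scale, size=size) * rng.uniform(size=size)


def _chiasma_events_batch(
    n: int, length: float, shape: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chiasma positions for ``n`` independent bundles on one chromosome.

    Returns (positions, bundle_index), positions unsorted across bundles but
    increasing within a bundle.
    """
    scale = 1.0 / (CHIASMA_RATE * shape)  # mean interarrival 1/2 Morgan
    # enough columns for the bulk of bundles; the loop below extends the rest
    k = max(3, int(np.ceil(CHIASMA_RATE * length * 2.5)) + 2)
    first = _stationary_first_event(shape, scale, n, rng)
    inter = rng.gamma(shape, scale, size=(n, k - 1))
    events = np.cumsum(np.concatenate([first[:, None], inter], axis=1), axis=1)
    # extend the rare bundles whose last drawn event is still inside [0, L)
    while True:
        short = events[:, -1] < length
        if not short.any():
            break
        w = events.shape[1]
        extra = np.cumsum(
            rng.gamma(shape, scale, size=(int(short.sum()), k - 1)), axis=1
        )
        events = np.concatenate([events, np.full((n, k - 1), np.inf)], axis=1)
        events[short, w:] = events[short, w - 1][:, None] + extra
    keep = events < length
    # no chromatid interference: each chiasma hits a given chromatid w.p. 1/2
    keep &= rng.random(size=events.shape) < 0.5
    bundle, _ = np.nonzero(keep)
    return events[keep], bundle


def sample_crossovers(
    length: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Crossover positions for one gamete on one chromosome (sorted, Morgans).

    A stationary gamma renewal chiasma process (intensity 2 per Morgan,
    gamma shape ``shape``) is thinned by 1/2, giving an expected 1 crossover
    per Morgan with interference controlled by ``shape``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    pos, _ = _chiasma_events_batch(1, length, shape, rng)
    return np.sort(pos)


def crossover_counts(
    n: int, length: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Crossover counts for ``n`` independent meioses of one chromosome."""
    if length <= 0 or shape <= 0:
        raise ValueError("length and shape must be positive")
    _, bundle = _chiasma_events_batch(n, length, shape, rng)
    return np.bincount(bundle, minlength=n)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True)
    def _apply_crossovers(pop, parent_idx, starts, bp, bp_off, chr_off, out):
        n_chrom = chr_off.shape[0] - 1
        for b in range(out.shape[0]):
            p = parent_idx[b]
            k = bp_off[b]
            k_end = bp_off[b + 1]
            for c in range(n_chrom):
                phase = starts[b, c]
                a = chr_off[c]
                end = chr_off[c + 1]
                while k < k_end and bp[k] < end:
                    e = bp[k]
                    if e > a:
                        out[b, a:e] = pop[p, phase, a:e]
                        a = e
                    phase = 1 - phase
                    k += 1
                out[b, a:end] = pop[p, phase, a:end]

else:  # pragma: no cover - numpy fallback, same contract

    def _apply_crossovers(pop, parent_idx, starts, bp, bp_off, chr_off, out):
        n_chrom = chr_off.shape[0] - 1
        for b in range(out.shape[0]):
            p = parent_idx[b]
            k = bp_off[b]
            k_end = bp_off[b + 1]
            for c in range(n_chrom):
                phase = starts[b, c]
                a = chr_off[c]
                end = chr_off[c + 1]
                while k < k_end and bp[k] < end:
                    e = bp[k]
                    if e > a:
                        out[b, a:e] = pop[p, phase, a:e]
                        a = e
                    phase = 1 - phase
                    k += 1
                out[b, a:end] = pop[p, phase, a:end]


@dataclass
class CrossoverRecipes:
    """Sampled meioses as map-level events, independent of any site set.

    ``positions``/``chroms`` hold the crossover positions (Morgans) of all
    gametes flattened and sorted by (gamete, chromosome, position), with
    per-gamete ``offsets``; ``starts`` gives the starting haplotype of every
    (gamete, chromosome).  The same recipe can be applied to any subset of
    the map's sites and always yields consistent gametes.
    """

    positions: np.ndarray
    chroms: np.ndarray
    offsets: np.ndarray
    starts: np.ndarray

    def __len__(self) -> int:
        return self.starts.shape[0]

    def subset(self, gametes: np.ndarray) -> "CrossoverRecipes":
        gametes = np.asarray(gametes, dtype=np.int64)
        counts = np.diff(self.offsets)[gametes]
        take = np.concatenate(
            [np.arange(self.offsets[g], self.offsets[g + 1]) for g in gametes]
        ) if counts.sum() else np.empty(0, dtype=np.int64)
        return CrossoverRecipes(
            positions=self.positions[take],
            chroms=self.chroms[take],
            offsets=np.concatenate([[0], np.cumsum(counts)]).astype(np.int64),
            starts=self.starts[gametes],
        )


def sample_meiosis_recipes(
    n_gametes: int,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    interference_shape: float = 2.63,
) -> CrossoverRecipes:
    """Sample crossover positions and starting phases for a batch of meioses."""
    n_chrom = genetic_map.n_chromosomes
    if np.all(genetic_map.lengths == genetic_map.lengths[0]):
        # equal-length chromosomes: one batched draw over gamete x chromosome
        pos, flat = _chiasma_events_batch(
            n_gametes * n_chrom, float(genetic_map.lengths[0]),
            interference_shape, rng,
        )
        xo_g, xo_c = flat // n_chrom, flat % n_chrom
        xo_pos = pos
    else:
        xo_pos_parts, xo_g_parts, xo_c_parts = [], [], []
        for c in range(n_chrom):
            pos, bundle = _chiasma_events_batch(
                n_gametes, float(genetic_map.lengths[c]), interference_shape, rng
            )
            xo_pos_parts.append(pos)
            xo_g_parts.append(bundle)
            xo_c_parts.append(np.full(pos.shape, c, dtype=np.int64))
        xo_pos = np.concatenate(xo_pos_parts)
        xo_g = np.concatenate(xo_g_parts)
        xo_c = np.concatenate(xo_c_parts)
    order = np.lexsort((xo_pos, xo_c, xo_g))
    offsets = np.concatenate(
        [[0], np.cumsum(np.bincount(xo_g, minlength=n_gametes))]
    ).astype(np.int64)
    return CrossoverRecipes(
        positions=xo_pos[order],
        chroms=xo_c[order],
        offsets=offsets,
        starts=rng.integers(0, 2, size=(n_gametes, n_chrom), dtype=np.uint8),
    )


def apply_meiosis_recipes(
    pop: np.ndarray,
    parent_idx: np.ndarray,
    recipes: CrossoverRecipes,
    genetic_map: GeneticMap,
    sites: np.ndarray | None = None,
) -> np.ndarray:
    """Materialize gametes from sampled recipes, optionally at a site subset.

    With ``sites`` given (sorted flat indices), ``pop`` must hold exactly
    those columns and the returned gametes cover them only; recombination
    between the retained sites is identical to the full-map result.
    """
    pop = np.ascontiguousarray(pop, dtype=np.uint8)
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    if pop.ndim != 3 or pop.shape[1] != 2:
        raise ValueError("pop must have shape (n, 2, n_sites)")
    if sites is None:
        flat_positions = genetic_map.flat_positions
        chrom_of_site = genetic_map.chrom_of_site
        chr_offsets = genetic_map.chr_offsets
    else:
        sites = np.asarray(sites, dtype=np.int64)
        flat_positions = genetic_map.flat_positions[sites]
        chrom_of_site = genetic_map.chrom_of_site[sites]
        chr_offsets = np.concatenate(
            [[0], np.cumsum(np.bincount(chrom_of_site, minlength=genetic_map.n_chromosomes))]
        ).astype(np.int64)
    n_sites = flat_positions.shape[0]
    if pop.shape[2] != n_sites:
        raise ValueError("haplotype columns do not match the requested sites")
    n_gametes = parent_idx.shape[0]
    if len(recipes) != n_gametes:
        raise ValueError("one recipe per gamete required")

    # crossover positions -> flat breakpoint site indices (shared coordinate
    # axis: chromosome-strided positions keep one global searchsorted valid)
    stride = float(genetic_map.lengths.max()) + 1.0
    site_coord = chrom_of_site * stride + flat_positions
    bp = np.searchsorted(site_coord, recipes.chroms * stride + recipes.positions)
    # a crossover past the last retained site of its chromosome is a no-op
    in_chrom = bp < chr_offsets[recipes.chroms + 1]
    bp = np.ascontiguousarray(bp[in_chrom])
    gamete_of_bp = np.repeat(np.arange(n_gametes), np.diff(recipes.offsets))[in_chrom]
    bp_off = np.concatenate(
        [[0], np.cumsum(np.bincount(gamete_of_bp, minlength=n_gametes))]
    ).astype(np.int64)

    out = np.empty((n_gametes, n_sites), dtype=np.uint8)
    _apply_crossovers(pop, parent_idx, recipes.starts, bp, bp_off, chr_offsets, out)
    return out


def meiosis_batch(
    pop: np.ndarray,
    parent_idx: np.ndarray,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    interference_shape: float = 2.63,
) -> np.ndarray:
    """Produce one recombinant gamete per entry of ``parent_idx``.

    ``pop`` holds diploid haplotypes with shape (n_individuals, 2, n_sites);
    gamete ``b`` is a recombinant of ``pop[parent_idx[b]]``.  Chromosomes
    recombine independently; each starts on a random haplotype and switches
    haplotype at every crossover.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    recipes = sample_meiosis_recipes(
        parent_idx.shape[0], genetic_map, rng, interference_shape
    )
    return apply_meiosis_recipes(pop, parent_idx, recipes, genetic_map)


def meiosis(
    parent: np.ndarray,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    interference_shape: float = 2.63,
) -> np.ndarray:
    """One gamete (n_sites,) from a diploid parent given as (2, n_sites)."""
    parent = np.asarray(parent, dtype=np.uint8)
    if parent.shape != (2, genetic_map.n_sites):
        raise ValueError("parent must have shape (2, n_sites) matching the map")
    return meiosis_batch(
        parent[None], np.zeros(1, dtype=np.int64), genetic_map, rng,
        interference_shape,
    )[0]


def cross(female, male) -> np.ndarray:
    """Fuse two gametophyte genomes into a diploid sporophyte (2, n_sites).

    Arguments may be raw haplotype arrays or objects exposing ``haplotype``
    and ``sex`` attributes; when sexes are available they must differ
    (one "F", one "M").
    """
    f_sex = getattr(female, "sex", None)
    m_sex = getattr(male, "sex", None)
    if f_sex is not None and m_sex is not None and f_sex == m_sex:
        raise ValueError(f"cannot cross two gametophytes of sex {f_sex!r}")
    f_hap = np.asarray(getattr(female, "haplotype", female), dtype=np.uint8)
    m_hap = np.asarray(getattr(male, "haplotype", male), dtype=np.uint8)
    if f_hap.shape != m_hap.shape or f_hap.ndim != 1:
        raise ValueError("gametophyte haplotypes must be 1-D and equal length")
    return np.stack([f_hap, m_hap])


# ---------------------------------------------------------------------------
# Additive trait
# ---------------------------------------------------------------------------


def error_variance_for_h2(h2: float, genetic_variance: float = 1.0) -> float:
    """Error variance implied by h2 = var_A / (var_A + var_E)."""
    if not 0 < h2 <= 1:
        raise ValueError("heritability must be in (0, 1]")
    return genetic_variance * (1.0 - h2) / h2


@dataclass
class TraitModel:
    """Additive polygenic trait: QTL flat site indices, effects and scaling.

    Effects are scaled so the founder sporophyte cohort used at construction
    has genetic mean 0 and variance ``genetic_variance_target``.  Haploid
    (gametophyte) genetic values are reported on the doubled-haploid scale,
    i.e. the value of the fully homozygous sporophyte the gametophyte would
    found, so gametophyte and sporophyte cohorts share one scale.
    """

    qtl_sites: np.ndarray
    effects: np.ndarray
    intercept: float
    heritability: float
    error_variance: float
    genetic_variance_target: float = 1.0

    def __post_init__(self) -> None:
        self.qtl_sites = np.asarray(self.qtl_sites, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if self.qtl_sites.shape != self.effects.shape:
            raise ValueError("one effect per QTL site required")
        if self.error_variance < 0:
            raise ValueError("error variance must be non-negative")
        implied = self.genetic_variance_target / (
            self.genetic_variance_target + self.error_variance
        )
        if abs(implied - self.heritability) > 1e-6:
            raise ValueError(
                "stored h2 inconsistent with variance components: "
                f"h2={self.heritability}, implied={implied}"
            )

    @classmethod
    def from_founders(
        cls,
        founder_haplotypes: np.ndarray,
        qtl_sites: np.ndarray,
        heritability: float,
        rng: np.random.Generator,
        genetic_variance_target: float = 1.0,
    ) -> "TraitModel":
        """Draw iid standard-normal QTL effects, then rescale affinely so the
        founder cohort has genetic mean 0 and variance exactly the target."""
        qtl_sites = np.asarray(qtl_sites, dtype=np.int64)
        raw = rng.standard_normal(qtl_sites.size)
        dosage = founder_haplotypes[:, :, qtl_sites].sum(axis=1).astype(np.float64)
        values = dosage @ raw
        sd = values.std()
        if sd == 0:
            raise ValueError("founder QTL dosages are monomorphic; cannot scale trait")
        scale = np.sqrt(genetic_variance_target) / sd
        effects = raw * scale
        intercept = -float((dosage @ effects).mean())
        return cls(
            qtl_sites=qtl_sites,
            effects=effects,
            intercept=intercept,
            heritability=heritability,
            error_variance=error_variance_for_h2(
                heritability, genetic_variance_target
            ),
            genetic_variance_target=genetic_variance_target,
        )


def genetic_value_diploid(haplotypes: np.ndarray, trait: TraitModel) -> np.ndarray:
    """Genetic values for diploids given as (n, 2, n_sites) or (2, n_sites)."""
    haplotypes = np.asarray(haplotypes)
    single = haplotypes.ndim == 2
    if single:
        haplotypes = haplotypes[None]
    dosage = haplotypes[:, :, trait.qtl_sites].sum(axis=1, dtype=np.float32)
    values = trait.intercept + (dosage @ trait.effects.astype(np.float32)).astype(
        np.float64
    )
    return values[0] if single else values


def genetic_value_haploid(haplotypes: np.ndarray, trait: TraitModel) -> np.ndarray:
    """Doubled-haploid-scale genetic values for haploids (n, n_sites) or (n_sites,)."""
    haplotypes = np.asarray(haplotypes)
    single = haplotypes.ndim == 1
    if single:
        haplotypes = haplotypes[None]
    dosage = haplotypes[:, trait.qtl_sites].astype(np.float32)
    values = trait.intercept + 2.0 * (
        dosage @ trait.effects.astype(np.float32)
    ).astype(np.float64)
    return values[0] if single else values


def genetic_value(genome: np.ndarray, trait: TraitModel, ploidy: int | None = None):
    """Genetic value of a haploid or diploid genome.

    Ploidy is inferred from the array shape; pass ``ploidy`` explicitly for
    the ambiguous case of two haploids stacked as (2, n_sites).
    """
    genome = np.asarray(genome)
    if ploidy is None:
        ploidy = 2 if (genome.ndim >= 2 and genome.shape[-2] == 2) else 1
    if ploidy == 2:
        return genetic_value_diploid(genome, trait)
    return genetic_value_haploid(genome, trait)


def phenotype(
    genetic_values: np.ndarray, error_variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Phenotype = genetic value + N(0, error_variance) plot deviation."""
    if error_variance < 0:
        raise ValueError("error variance must be non-negative")
    genetic_values = np.asarray(genetic_values, dtype=np.float64)
    if error_variance == 0:
        return genetic_values.copy()
    return genetic_values + rng.normal(
        0.0, np.sqrt(error_variance), size=genetic_values.shape
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_vcf(
    path,
    haplotypes: np.ndarray,
    genetic_map: GeneticMap,
    sample_ids: list[str] | None = None,
    morgans_per_bp: float = 1e-8,
) -> None:
    """Write genotypes as a plain-text VCF (v4.2).

    Diploids (n, 2, n_sites) are written as phased 0|1 calls, haploids
    (n, n_sites) as single-allele calls.  Physical coordinates are derived
    from map positions at ``morgans_per_bp`` (1 cM/Mb by default).
    """
    haplotypes = np.asarray(haplotypes)
    diploid = haplotypes.ndim == 3
    n = haplotypes.shape[0]
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=kelpsim\n')
        for c in range(genetic_map.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for s in range(genetic_map.n_sites):
            c = genetic_map.chrom_of_site[s]
            bp = int(round(genetic_map.flat_positions[s] / morgans_per_bp)) + 1
            if diploid:
                calls = [
                    f"{haplotypes[i, 0, s]}|{haplotypes[i, 1, s]}" for i in range(n)
                ]
            else:
                calls = [str(haplotypes[i, s]) for i in range(n)]
            fh.write(
                f"chr{c + 1}\t{bp}\tsite{s}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
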