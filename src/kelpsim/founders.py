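"""Founder population generator with drift-governed linkage disequilibrium.

The breeding-scheme simulations start from 1,000 founder sporophytes whose
background LD is controlled by an effective population size Ne.  Founders are
produced by a neutral forward-in-time burn-in: sites start at linkage
equilibrium with uniform minor-allele frequencies, a Wright-Fisher population
of Ne diploids random-mates (selfing allowed) for a configurable number of
generations so drift and recombination establish LD, and the burned-in
population is then expanded by random mating to the requested founder count.

At drift-recombination equilibrium the expected squared LD correlation
between loci at recombination rate c follows Sved's approximation
E[r2] ~ 1/(1 + 4*Ne*c), which is the calibration check applied to the
generated founders (plus a finite-sample inflation of order 1/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import GeneticMap, GenomeParams, meiosis_batch

__all__ = [
    "FounderConfig",
    "FounderPopulation",
    "LDSummary",
    "simulate_founders",
    "mean_r2",
    "sved_expected_r2",
    "estimate_Ne",
]


@dataclass(frozen=True)
class FounderConfig:
    effective_population_size: int = 60
    n_founders: int = 1000
    burn_in_generations: int = 100
    initial_maf_range: tuple[float, float] = (0.05, 0.5)
    segregating_maf_min: float = 0.01
    #: sites simulated per site retained; "auto" anticipates drift fixation
    site_oversampling: float | str = "auto"
    max_redraws: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.effective_population_size < 2:
            raise ValueError("Ne must be at least 2")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.burn_in_generations < 0:
            raise ValueError("burn-in generations must be non-negative")
        lo, hi = self.initial_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("initial MAF range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class FounderPopulation:
    """Founder sporophytes plus the retained map and site designations."""

    haplotypes: np.ndarray  # (n_founders, 2, n_sites) uint8
    genetic_map: GeneticMap
    qtl_sites: np.ndarray  # flat indices into the retained sites
    marker_sites: np.ndarray  # flat indices, disjoint from qtl_sites
    config: FounderConfig

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Diploid 0/1/2 dosages, optionally restricted to flat site indices."""
        d = self.haplotypes.sum(axis=1)
        return d if sites is None else d[:, np.asarray(sites)]

    def metadata_frame(self, trait=None):
        """Founder table: id, cohort label and (with a trait) genetic value."""
        import pandas as pd

        from .genetics import genetic_value_diploid

        frame = pd.DataFrame(
            {
                "id": [f"founder{i}" for i in range(self.n_founders)],
                "cohort": "founder",
            }
        )
        if trait is not None:
            frame["genetic_value"] = genetic_value_diploid(self.haplotypes, trait)
        return frame


def _random_mate(
    pop: np.ndarray,
    n_offspring: int,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    interference_shape: float,
) -> np.ndarray:
    """One generation of random union of gametes (selfing allowed)."""
    n = pop.shape[0]
    parents = rng.integers(0, n, size=2 * n_offspring)
    gametes = meiosis_batch(pop, parents, genetic_map, rng, interference_shape)
    return np.stack(
        [gametes[:n_offspring], gametes[n_offspring:]], axis=1
    )


def simulate_founders(
    cfg: FounderConfig,
    gp: GenomeParams,
    rng: np.random.Generator | None = None,
) -> FounderPopulation:
    """Simulate the founder sporophyte population.

    Sites are oversampled relative to the requested count so that, after
    drift during burn-in, each chromosome still carries enough segregating
    sites; the requested number is then drawn at random among sites with
    founder MAF >= ``segregating_maf_min``, and QTL/marker designations are
    disjoint random subsets of the retained sites.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ne = cfg.effective_population_size
    if cfg.site_oversampling == "auto":
        # expected fraction of sites still segregating after g generations of
        # drift scales with the heterozygosity retention exp(-g/(2Ne))
        survive = max(
            0.2, 0.95 * np.exp(-cfg.burn_in_generations / (2.0 * ne)) + 0.02
        )
        oversample = float(min(4.0, max(1.15, 1.25 / survive)))
    else:
        oversample = float(cfg.site_oversampling)
    for attempt in range(cfg.max_redraws):
        n_sim_sites = int(np.ceil(gp.sites_per_chromosome * oversample))
        sim_params = GenomeParams(
            n_chromosomes=gp.n_chromosomes,
            sites_per_chromosome=n_sim_sites,
            qtl_per_chromosome=min(gp.qtl_per_chromosome, n_sim_sites),
            chromosome_length=gp.chromosome_length,
            interference_shape=gp.interference_shape,
        )
        genetic_map = GeneticMap.random(sim_params, rng)

        # linkage-equilibrium start: per-site allele frequencies, iid haplotypes
        freqs = rng.uniform(*cfg.initial_maf_range, size=genetic_map.n_sites)
        haps = (
            rng.random(size=(2 * ne, genetic_map.n_sites)) < freqs
        ).astype(np.uint8)
        pop = np.stack([haps[:ne], haps[ne:]], axis=1)

        for _ in range(cfg.burn_in_generations):
            pop = _random_mate(pop, ne, genetic_map, rng, gp.interference_shape)
        founders = _random_mate(
            pop, cfg.n_founders, genetic_map, rng, gp.interference_shape
        )

        freq = founders.sum(axis=(0, 1)) / (2.0 * cfg.n_founders)
        maf = np.minimum(freq, 1.0 - freq)
        keep_parts = []
        enough = True
        for c in range(genetic_map.n_chromosomes):
            lo, hi = genetic_map.chr_offsets[c], genetic_map.chr_offsets[c + 1]
            candidates = lo + np.nonzero(maf[lo:hi] >= cfg.segregating_maf_min)[0]
            if candidates.size < gp.sites_per_chromosome:
                enough = False
                break
            keep_parts.append(
                np.sort(
                    rng.choice(candidates, gp.sites_per_chromosome, replace=False)
                )
            )
        if enough:
            keep = np.concatenate(keep_parts)
            retained_map = genetic_map.subset(keep)
            retained = np.ascontiguousarray(founders[:, :, keep])
            qtl_parts, marker_parts = [], []
            for c in range(gp.n_chromosomes):
                lo = c * gp.sites_per_chromosome
                local = rng.permutation(gp.sites_per_chromosome)
                qtl_parts.append(np.sort(lo + local[: gp.qtl_per_chromosome]))
                marker_parts.append(np.sort(lo + local[gp.qtl_per_chromosome:]))
            return FounderPopulation(
                haplotypes=retained,
                genetic_map=retained_map,
                qtl_sites=np.concatenate(qtl_parts),
                marker_sites=np.concatenate(marker_parts),
                config=cfg,
            )
        oversample *= 1.5
    raise RuntimeError(
        f"fewer than {gp.sites_per_chromosome} sites per chromosome segregate at "
        f"MAF >= {cfg.segregating_maf_min} after {cfg.max_redraws} redraws "
        f"(Ne={ne}, burn-in={cfg.burn_in_generations}); increase site_oversampling"
    )


# ---------------------------------------------------------------------------
# LD summaries and the Sved relation
# ---------------------------------------------------------------------------


@dataclass
class LDSummary:
    """Mean squared LD correlation by recombination-rate bin.

    The last entry of ``bin_c``/``bin_mean_r2``/``bin_count`` is the unlinked
    bin (pairs on different chromosomes, c = 0.5); the preceding bins cover
    within-chromosome pairs by Kosambi-transformed recombination fraction.
    """

    bin_c: np.ndarray
    bin_mean_r2: np.ndarray
    bin_count: np.ndarray
    unlinked_mean_r2: float
    overall_mean_r2: float


def _pair_r2(dosages: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns for the given pairs.

    Monomorphic pairs (zero variance) return NaN and are excluded by callers.
    """
    r2 = np.empty(ia.size)
    n = dosages.shape[0]
    x = dosages - dosages.mean(axis=0)
    var = (x**2).sum(axis=0)
    chunk = 8192
    for s in range(0, ia.size, chunk):
        a, b = ia[s : s + chunk], ib[s : s + chunk]
        cov = np.einsum("ij,ij->j", x[:, a], x[:, b])
        denom = var[a] * var[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[s : s + chunk] = cov**2 / denom
    return r2


def mean_r2(
    dosages: np.ndarray,
    genetic_map: GeneticMap,
    bin_edges: np.ndarray | None = None,
    pairs_per_chromosome: int = 1000,
    n_unlinked_pairs: int = 20000,
    rng: np.random.Generator | None = None,
) -> LDSummary:
    """LD summary over sampled marker pairs.

    Within-chromosome pairs are binned by the Kosambi recombination fraction
    c = tanh(2d)/2 of their map distance d; pairs on different chromosomes
    form the unlinked (c = 0.5) bin.  Pair sampling keeps the cost bounded on
    dense genomes; monomorphic pairs are excluded.
    """
    if rng is None:
        rng = np.random.default_rng()
    dosages = np.asarray(dosages, dtype=np.float64)
    if dosages.shape[0] < 2 or dosages.shape[1] < 2:
        raise ValueError("need at least 2 individuals and 2 markers")
    if dosages.shape[1] != genetic_map.n_sites:
        raise ValueError("dosage columns do not match the map")
    if bin_edges is None:
        bin_edges = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
    bin_edges = np.asarray(bin_edges, dtype=np.float64)

    ia_parts, ib_parts, c_parts = [], [], []
    for c in range(genetic_map.n_chromosomes):
        lo, hi = genetic_map.chr_offsets[c], genetic_map.chr_offsets[c + 1]
        n_sites = hi - lo
        if n_sites < 2:
            continue
        a = rng.integers(lo, hi, size=pairs_per_chromosome)
        b = rng.integers(lo, hi, size=pairs_per_chromosome)
        ok = a != b
        a, b = a[ok], b[ok]
        d = np.abs(
            genetic_map.flat_positions[a] - genetic_map.flat_positions[b]
        )
        ia_parts.append(a)
        ib_parts.append(b)
        c_parts.append(0.5 * np.tanh(2.0 * d))
    if genetic_map.n_chromosomes > 1 and n_unlinked_pairs > 0:
        a = rng.integers(0, genetic_map.n_sites, size=n_unlinked_pairs)
        b = rng.integers(0, genetic_map.n_sites, size=n_unlinked_pairs)
        ok = genetic_map.chrom_of_site[a] != genetic_map.chrom_of_site[b]
        ia_parts.append(a[ok])
        ib_parts.append(b[ok])
        c_parts.append(np.full(int(ok.sum()), 0.5))
    ia = np.concatenate(ia_parts)
    ib = np.concatenate(ib_parts)
    c_pair = np.concatenate(c_parts)
    unlinked = c_pair == 0.5

    r2 = _pair_r2(dosages, ia, ib)
    ok = np.isfinite(r2)
    r2, c_pair, unlinked = r2[ok], c_pair[ok], unlinked[ok]

    bins = np.digitize(c_pair[~unlinked], bin_edges) - 1
    n_bins = bin_edges.size - 1
    bin_c = np.empty(n_bins + 1)
    bin_mean = np.full(n_bins + 1, np.nan)
    bin_count = np.zeros(n_bins + 1, dtype=np.int64)
    for k in range(n_bins):
        sel = bins == k
        bin_c[k] = 0.5 * (bin_edges[k] + bin_edges[k + 1])
        bin_count[k] = int(sel.sum())
        if bin_count[k]:
            bin_mean[k] = float(r2[~unlinked][sel].mean())
    bin_c[-1] = 0.5
    bin_count[-1] = int(unlinked.sum())
    unlinked_mean = float(r2[unlinked].mean()) if bin_count[-1] else np.nan
    bin_mean[-1] = unlinked_mean
    return LDSummary(
        bin_c=bin_c,
        bin_mean_r2=bin_mean,
        bin_count=bin_count,
        unlinked_mean_r2=unlinked_mean,
        overall_mean_r2=float(r2.mean()),
    )


def sved_expected_r2(Ne: float, c: float) -> float:
    """Sved's drift-recombination equilibrium expectation 1/(1 + 4*Ne*c)."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if not 0 < c <= 0.5:
        raise ValueError("recombination rate must be in (0, 0.5]")
    return 1.0 / (1.0 + 4.0 * Ne * c)


def estimate_Ne(mean_r2_value: float, c: float) -> float:
    """Invert Sved's formula: Ne = (1/E[r2] - 1) / (4c)."""
    if not 0 < mean_r2_value < 1:
        raise ValueError("mean r2 must be in (0, 1)")
    if not 0 < c <= 0.5:
        raise ValueError("recombination rate must be in (0, 0.5]")
    return (1.0 / mean_r2_value - 1.0) / (4.0 * c)
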