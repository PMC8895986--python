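"""The biphasic breeding-cycle engine.

One cycle alternates the two life-cycle phases: farm-evaluated diploid
sporophytes (SP) are selected (randomly or on phenotype, top 10%), each
selected SP releases ``n_gp`` haploid gametophytes (GP) by meiosis, GPs are
genotyped and ranked by GEBV from a ridge-regression BLUP model trained on
all previously phenotyped SP cohorts, the top ``num_cross/2`` of each sex are
kept, and two random bijections between the female and male lists create
``num_cross`` new sporophyte plots (each GP used in exactly 2 crosses,
selfing-equivalent pairs allowed).  The calendar convention: a cohort crossed
in year ``t`` is farm-evaluated in year ``t+1``; the routine scheme starts in
year 2; a 1-year cycle therefore runs a selection event every year and a
2-year cycle every second year.  Cycles are non-overlapping.

Per-year metrics (genetic mean, total genetic variance, GS accuracy) are
taken on the GP candidate cohort before GP selection and carried forward in
years without a new GP cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .founders import FounderPopulation
from .genetics import (
    CrossoverRecipes,
    GeneticMap,
    TraitModel,
    apply_meiosis_recipes,
    genetic_value_diploid,
    genetic_value_haploid,
    meiosis_batch,
    phenotype,
    sample_meiosis_recipes,
)
from .rrblup import RRBLUPFit, TrainingSet, fit_rrblup, gs_accuracy, predict_gebv

__all__ = [
    "SchemeConfig",
    "Gametophyte",
    "GametophyteCohort",
    "SporophyteCohort",
    "MetricsRecord",
    "SchemeError",
    "select_sporophytes",
    "produce_gametophytes",
    "select_gametophytes",
    "make_crosses",
    "run_scheme",
    "selection_intensity_theoretical",
    "selection_intensity_empirical",
]

SEX_LABELS = ("F", "M")


class SchemeError(RuntimeError):
    """A breeding-scheme configuration turned out infeasible at run time."""


@dataclass(frozen=True)
class SchemeConfig:
    cycle_time: int = 2  # years per breeding cycle (1 or 2)
    num_cross: int = 400  # SP plots made and evaluated per cohort
    select_sp: str = "random"  # "random" or "pheno"
    n_gp: int = 24  # gametophytes per selected sporophyte
    sp_selected_fraction: float = 0.10
    crosses_per_gp: int = 2
    horizon: int = 10  # years simulated
    founder_gp_per_sp: int = 2

    def __post_init__(self) -> None:
        if self.cycle_time < 1:
            raise ValueError("cycle_time must be at least 1 year")
        if self.num_cross < 2 or self.num_cross % 2:
            raise ValueError("num_cross must be even and at least 2")
        if self.select_sp not in ("random", "pheno"):
            raise ValueError("select_sp must be 'random' or 'pheno'")
        if self.n_gp < 1 or self.founder_gp_per_sp < 1:
            raise ValueError("gametophyte counts must be positive")
        if not 0 < self.sp_selected_fraction <= 1:
            raise ValueError("sp_selected_fraction must be in (0, 1]")
        if self.horizon < self.cycle_time:
            raise ValueError("horizon must cover at least one cycle")
        n_selected = int(self.sp_selected_fraction * self.num_cross)
        if n_selected * self.n_gp < self.num_cross // self.crosses_per_gp * 2:
            raise ValueError(
                "expected gametophyte supply cannot cover num_cross crosses"
            )


@dataclass
class Gametophyte:
    """A single haploid selection candidate (view into a cohort)."""

    haplotype: np.ndarray
    sex: str
    parent_sporophyte: int
    genetic_value: float
    gebv: float | None = None


@dataclass
class GametophyteCohort:
    haplotypes: np.ndarray  # (n, n_sites) uint8 (possibly a site subset)
    sex: np.ndarray  # (n,) uint8: 0 = F, 1 = M
    parent_sporophyte: np.ndarray  # (n,) index into the parent cohort
    genetic_values: np.ndarray  # doubled-haploid scale
    year: int
    gebv: np.ndarray | None = None
    #: when haplotypes cover only a site subset: the flat indices covered,
    #: and the crossover recipes allowing exact full-genome reconstruction
    sites: np.ndarray | None = None
    recipes: CrossoverRecipes | None = None
    #: cached float32 view of ``haplotypes`` for repeated linear scoring
    dense32: np.ndarray | None = None

    def __len__(self) -> int:
        return self.haplotypes.shape[0]

    def individual(self, i: int) -> Gametophyte:
        return Gametophyte(
            haplotype=self.haplotypes[i],
            sex=SEX_LABELS[self.sex[i]],
            parent_sporophyte=int(self.parent_sporophyte[i]),
            genetic_value=float(self.genetic_values[i]),
            gebv=None if self.gebv is None else float(self.gebv[i]),
        )


@dataclass
class SporophyteCohort:
    haplotypes: np.ndarray  # (n, 2, n_sites) uint8
    genetic_values: np.ndarray
    year: int  # evaluation (phenotyping) year
    phenotypes: np.ndarray | None = None
    parent_f: np.ndarray | None = None  # gametophyte indices
    parent_m: np.ndarray | None = None
    parent_f_sporophyte: np.ndarray | None = None
    parent_m_sporophyte: np.ndarray | None = None

    def __len__(self) -> int:
        return self.haplotypes.shape[0]

    @classmethod
    def from_founders(
        cls, founders: FounderPopulation, trait: TraitModel
    ) -> "SporophyteCohort":
        return cls(
            haplotypes=founders.haplotypes,
            genetic_values=genetic_value_diploid(founders.haplotypes, trait),
            year=0,
        )


@dataclass
class MetricsRecord:
    year: int
    mean_g: float
    var_g: float
    accuracy: float
    new_cohort: bool = True


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def select_sporophytes(
    cohort: SporophyteCohort,
    method: str,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the selected sporophytes (top fraction or random sample)."""
    n = len(cohort)
    if n == 0:
        raise SchemeError("cannot select from an empty sporophyte cohort")
    k = int(fraction * n)
    if k < 1:
        raise SchemeError(f"selected fraction {fraction} keeps no sporophytes of {n}")
    if method == "random":
        return np.sort(rng.choice(n, size=k, replace=False))
    if method == "pheno":
        if cohort.phenotypes is None:
            raise SchemeError("phenotypic selection requires phenotypes")
        # stable sort: ties broken by id order
        order = np.argsort(-cohort.phenotypes, kind="stable")
        return np.sort(order[:k])
    raise ValueError(f"unknown selection method {method!r}")


def produce_gametophytes(
    cohort: SporophyteCohort,
    selected: np.ndarray,
    n_gp: int,
    genetic_map: GeneticMap,
    trait: TraitModel,
    rng: np.random.Generator,
    year: int,
    interference_shape: float = 2.63,
    restrict_sites: np.ndarray | None = None,
) -> GametophyteCohort:
    """Release ``n_gp`` gametophytes per selected sporophyte.

    Each gametophyte is an independent meiosis product; sexes are assigned
    independently F/M with probability 1/2.  With ``restrict_sites`` the
    candidate haplotypes are materialized at those sites only (which must
    include the QTL); the random draws are identical either way.
    """
    if n_gp < 1:
        raise ValueError("n_gp must be positive")
    selected = np.asarray(selected, dtype=np.int64)
    parent_idx = np.repeat(selected, n_gp)
    if restrict_sites is None:
        haps = meiosis_batch(
            cohort.haplotypes, parent_idx, genetic_map, rng, interference_shape
        )
        return GametophyteCohort(
            haplotypes=haps,
            sex=rng.integers(0, 2, size=parent_idx.size, dtype=np.uint8),
            parent_sporophyte=parent_idx,
            genetic_values=genetic_value_haploid(haps, trait),
            year=year,
        )
    # fast path: materialize candidates only at the sites that matter for
    # ranking (markers + QTL); the recipes allow exact reconstruction of the
    # full genomes of whichever candidates are later selected for crossing
    restrict_sites = np.asarray(restrict_sites, dtype=np.int64)
    qtl_local = np.searchsorted(restrict_sites, trait.qtl_sites)
    if np.any(restrict_sites[qtl_local] != trait.qtl_sites):
        raise ValueError("restrict_sites must contain all QTL sites")
    recipes = sample_meiosis_recipes(
        parent_idx.size, genetic_map, rng, interference_shape
    )
    haps = apply_meiosis_recipes(
        np.ascontiguousarray(cohort.haplotypes[:, :, restrict_sites]),
        parent_idx,
        recipes,
        genetic_map,
        sites=restrict_sites,
    )
    # genetic values via a zero-padded effect vector over the retained
    # columns: one matmul, no per-QTL gather; the float32 matrix is kept for
    # GEBV scoring within the same cycle
    dense32 = haps.astype(np.float32)
    padded = np.zeros(restrict_sites.size, dtype=np.float32)
    padded[qtl_local] = trait.effects
    values = trait.intercept + 2.0 * (dense32 @ padded).astype(np.float64)
    return GametophyteCohort(
        haplotypes=haps,
        sex=rng.integers(0, 2, size=parent_idx.size, dtype=np.uint8),
        parent_sporophyte=parent_idx,
        genetic_values=values,
        year=year,
        sites=restrict_sites,
        recipes=recipes,
        dense32=dense32,
    )


def select_gametophytes(
    gps: GametophyteCohort,
    fit: RRBLUPFit | None,
    num_cross: int,
    marker_sites: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-sex truncation selection on GEBV; returns (female, male) indices.

    GEBVs are predicted from ``fit`` at ``marker_sites`` unless already
    attached to the cohort.  Ties are broken by id order.
    """
    per_sex = num_cross // 2
    if gps.gebv is None:
        if fit is None or marker_sites is None:
            raise SchemeError("GEBVs absent: need a fitted model and marker sites")
        cols = (
            marker_sites
            if gps.sites is None
            else np.searchsorted(gps.sites, marker_sites)
        )
        gps.gebv = predict_gebv(fit, gps.haplotypes[:, cols], ploidy=1)
    chosen = []
    for sex_code, label in enumerate(SEX_LABELS):
        members = np.nonzero(gps.sex == sex_code)[0]
        if members.size < per_sex:
            raise SchemeError(
                f"sex shortfall: need {per_sex} {label} gametophytes, have "
                f"{members.size}"
            )
        order = np.argsort(-gps.gebv[members], kind="stable")
        chosen.append(np.sort(members[order[:per_sex]]))
    return chosen[0], chosen[1]


def make_crosses(
    gps: GametophyteCohort,
    females: np.ndarray,
    males: np.ndarray,
    trait: TraitModel,
    rng: np.random.Generator,
    year: int,
) -> SporophyteCohort:
    """Cross the selected gametophytes into a new sporophyte cohort.

    Two independent uniform-random bijections between the female and male
    lists give every gametophyte exactly 2 crosses.  Selfing-equivalent pairs
    (both parents from one sporophyte) are allowed; if the two bijections
    produce any identical pair, the second is re-drawn once and then
    accepted.
    """
    females = np.asarray(females, dtype=np.int64)
    males = np.asarray(males, dtype=np.int64)
    if females.size != males.size or females.size == 0:
        raise SchemeError("need equally many female and male gametophytes")
    if np.any(gps.sex[females] != 0) or np.any(gps.sex[males] != 1):
        raise SchemeError("sex of provided parents does not match their list")
    n = females.size
    perm1 = rng.permutation(n)
    perm2 = rng.permutation(n)
    if np.any(perm1 == perm2):
        perm2 = rng.permutation(n)
    f_idx = np.concatenate([females, females])
    m_idx = np.concatenate([males[perm1], males[perm2]])
    haps = np.stack([gps.haplotypes[f_idx], gps.haplotypes[m_idx]], axis=1)
    # additivity: a cross's value is the mean of its parents' doubled-haploid
    # values (the diploid carries one copy of each parental haplotype)
    values = 0.5 * (gps.genetic_values[f_idx] + gps.genetic_values[m_idx])
    return SporophyteCohort(
        haplotypes=haps,
        genetic_values=values,
        year=year,
        parent_f=f_idx,
        parent_m=m_idx,
        parent_f_sporophyte=gps.parent_sporophyte[f_idx],
        parent_m_sporophyte=gps.parent_sporophyte[m_idx],
    )


# ---------------------------------------------------------------------------
# Selection intensity
# ---------------------------------------------------------------------------


def selection_intensity_theoretical(p: float) -> float:
    """Truncation selection intensity i = phi(z)/p under normality."""
    if not 0 < p <= 1:
        raise ValueError("selected fraction must be in (0, 1]")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def selection_intensity_empirical(
    selected: np.ndarray, cohort: np.ndarray
) -> float:
    """Standardized mean difference between selected and full cohort.

    The denominator is the cohort population standard deviation (ddof=0).
    """
    selected = np.asarray(selected, dtype=np.float64)
    cohort = np.asarray(cohort, dtype=np.float64)
    if selected.size == 0 or cohort.size == 0:
        raise ValueError("selected and cohort values must be nonempty")
    sd = cohort.std()
    if sd == 0:
        import warnings

        warnings.warn("zero cohort variance; selection intensity undefined")
        return np.nan
    return float((selected.mean() - cohort.mean()) / sd)


# ---------------------------------------------------------------------------
# The full scheme
# ---------------------------------------------------------------------------


def _materialized_parents(
    gps: GametophyteCohort,
    parent_cohort: SporophyteCohort,
    genetic_map: GeneticMap,
    females: np.ndarray,
    males: np.ndarray,
) -> tuple[GametophyteCohort, np.ndarray, np.ndarray]:
    """Full-genome view of the selected gametophytes of a subset cohort."""
    if gps.sites is None:
        return gps, females, males
    needed = np.concatenate([females, males])
    full = apply_meiosis_recipes(
        parent_cohort.haplotypes,
        gps.parent_sporophyte[needed],
        gps.recipes.subset(needed),
        genetic_map,
    )
    sub = GametophyteCohort(
        haplotypes=full,
        sex=gps.sex[needed],
        parent_sporophyte=gps.parent_sporophyte[needed],
        genetic_values=gps.genetic_values[needed],
        year=gps.year,
        gebv=None if gps.gebv is None else gps.gebv[needed],
    )
    f_local = np.arange(females.size)
    m_local = np.arange(females.size, needed.size)
    return sub, f_local, m_local


def _gp_metrics(gps: GametophyteCohort, year: int) -> MetricsRecord:
    acc = np.nan
    if gps.gebv is not None:
        acc = gs_accuracy(gps.gebv, gps.genetic_values)
    return MetricsRecord(
        year=year,
        mean_g=float(gps.genetic_values.mean()),
        var_g=float(gps.genetic_values.var()),
        accuracy=acc,
    )


def run_scheme(
    cfg: SchemeConfig,
    founders: FounderPopulation,
    trait: TraitModel,
    rng: np.random.Generator,
    marker_sites: np.ndarray | None = None,
    gs_lambda: float | str | None = None,
    record_pedigree: bool = False,
) -> list[MetricsRecord] | tuple[list[MetricsRecord], "pd.DataFrame"]:
    """Run one replicate of the breeding scheme over ``cfg.horizon`` years.

    Year 1: every founder sporophyte contributes ``founder_gp_per_sp``
    gametophytes without selection pressure; a random ``num_cross/2`` of each
    sex are crossed into cohort 1, evaluated in year 2.  Every evaluation
    year through the horizon then runs a gametophyte stage — the cohort
    joins the training set, sporophytes are selected, gametophytes released
    and GEBV-ranked (the GS model is refit on all accumulated records
    first) — and the winners are crossed whenever the resulting cohort can
    still be evaluated within the horizon.  With a 10-year horizon the
    1-year cycle therefore logs gametophyte cohorts in years 1-10 (8
    crossing rounds) and the 2-year cycle in years 1, 2, 4, 6, 8 and 10
    (4 crossing rounds).

    ``gs_lambda``: None fits the shrinkage ratio by REML each cycle;
    ``"auto"`` uses the heuristic m * sigma_e^2 / sigma_a^2; a float fixes it.
    """
    genetic_map = founders.genetic_map
    shape = 2.63
    if marker_sites is None:
        marker_sites = founders.marker_sites
    marker_sites = np.asarray(marker_sites, dtype=np.int64)
    if gs_lambda == "auto":
        gs_lambda = (
            marker_sites.size * trait.error_variance / trait.genetic_variance_target
        )

    founder_cohort = SporophyteCohort.from_founders(founders, trait)
    train = TrainingSet(marker_sites.size)
    records: dict[int, MetricsRecord] = {}
    pedigree_rows: list[dict] = []

    # candidates are ranked on markers and scored on QTL; their haplotypes
    # are materialized at those sites only until selected for crossing
    work_sites = np.union1d(marker_sites, trait.qtl_sites)
    if work_sites.size >= genetic_map.n_sites:
        work_sites = None
        marker_cols = marker_sites
    else:
        marker_cols = np.searchsorted(work_sites, marker_sites)

    # year 1: founder gametophytes, no selection pressure
    gps = produce_gametophytes(
        founder_cohort,
        np.arange(len(founder_cohort)),
        cfg.founder_gp_per_sp,
        genetic_map,
        trait,
        rng,
        year=1,
        interference_shape=shape,
        restrict_sites=work_sites,
    )
    records[1] = _gp_metrics(gps, 1)
    per_sex = cfg.num_cross // 2
    females = np.nonzero(gps.sex == 0)[0]
    males = np.nonzero(gps.sex == 1)[0]
    if females.size < per_sex or males.size < per_sex:
        raise SchemeError(
            "founder gametophyte supply cannot cover the first crossing round"
        )
    f_sel = np.sort(rng.choice(females, size=per_sex, replace=False))
    m_sel = np.sort(rng.choice(males, size=per_sex, replace=False))
    parents, f_loc, m_loc = _materialized_parents(
        gps, founder_cohort, genetic_map, f_sel, m_sel
    )
    cohort = make_crosses(parents, f_loc, m_loc, trait, rng, year=2)
    cohort.phenotypes = phenotype(cohort.genetic_values, trait.error_variance, rng)

    t = 2
    while t <= cfg.horizon:
        # cohort evaluated in year t joins the training population
        train.add_cohort(
            cohort.haplotypes[:, :, marker_sites].sum(axis=1),
            cohort.phenotypes,
            year=t,
        )
        if record_pedigree:
            pedigree_rows.extend(
                {
                    "year": t,
                    "child": i,
                    "parent_f_sporophyte": int(cohort.parent_f_sporophyte[i]),
                    "parent_m_sporophyte": int(cohort.parent_m_sporophyte[i]),
                }
                for i in range(len(cohort))
            )
        selected = select_sporophytes(
            cohort, cfg.select_sp, cfg.sp_selected_fraction, rng
        )
        gps = produce_gametophytes(
            cohort, selected, cfg.n_gp, genetic_map, trait, rng, year=t,
            interference_shape=shape, restrict_sites=work_sites,
        )
        fit = fit_rrblup(train, lambda_=gs_lambda)
        if gps.dense32 is not None:
            # same linear score as predict_gebv, on the cached float32 matrix
            # with marker effects zero-padded over the work-site columns
            padded_u = np.zeros(gps.haplotypes.shape[1], dtype=np.float32)
            padded_u[marker_cols] = fit.marker_effects
            offset = fit.intercept - float(fit.marker_means @ fit.marker_effects)
            gps.gebv = offset + 2.0 * (gps.dense32 @ padded_u).astype(np.float64)
            gps.dense32 = None
        else:
            gps.gebv = predict_gebv(fit, gps.haplotypes[:, marker_cols], ploidy=1)
        records[t] = _gp_metrics(gps, t)
        if t + cfg.cycle_time > cfg.horizon:
            # terminal gametophyte stage: the year-t harvest still releases
            # and ranks gametophytes, but their crosses would be evaluated
            # beyond the horizon
            break
        f_sel, m_sel = select_gametophytes(gps, fit, cfg.num_cross)
        parents, f_loc, m_loc = _materialized_parents(
            gps, cohort, genetic_map, f_sel, m_sel
        )
        cohort = make_crosses(
            parents, f_loc, m_loc, trait, rng, year=t + cfg.cycle_time
        )
        cohort.phenotypes = phenotype(
            cohort.genetic_values, trait.error_variance, rng
        )
        t += cfg.cycle_time

    # carry metrics forward through years without a new gametophyte cohort
    out: list[MetricsRecord] = []
    last: MetricsRecord | None = None
    for year in range(1, cfg.horizon + 1):
        if year in records:
            last = records[year]
            out.append(last)
        else:
            out.append(
                MetricsRecord(
                    year=year,
                    mean_g=last.mean_g,
                    var_g=last.var_g,
                    accuracy=last.accuracy,
                    new_cohort=False,
                )
            )
    if record_pedigree:
        import pandas as pd

        return out, pd.DataFrame(pedigree_rows)
    return out
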