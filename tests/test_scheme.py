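"""Breeding-cycle engine: stage operations, calendars, selection intensity."""

import numpy as np
import pytest
from scipy import stats

import kelpsim as ks
from kelpsim.scheme import (
    SchemeError,
    make_crosses,
    produce_gametophytes,
    select_gametophytes,
    select_sporophytes,
)


@pytest.fixture
def gp_cohort(small_founders, small_trait, rng):
    cohort = ks.SporophyteCohort.from_founders(small_founders, small_trait)
    return produce_gametophytes(
        cohort,
        np.arange(60),
        8,
        small_founders.genetic_map,
        small_trait,
        rng,
        year=1,
    )


class TestSelectionIntensity:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.10, 1.75),  # top 10% of sporophyte plots
            (1 / 2.4, 0.94),  # gametophyte stage, 24 per sporophyte
            (1 / 9.6, 1.74),  # gametophyte stage, 96 per sporophyte
        ],
    )
    def test_theoretical_values(self, p, expected):
        assert round(ks.selection_intensity_theoretical(p), 2) == expected

    def test_no_selection_limit(self):
        assert ks.selection_intensity_theoretical(1.0) == 0.0

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.1])
    def test_invalid_fraction(self, p):
        with pytest.raises(ValueError):
            ks.selection_intensity_theoretical(p)

    def test_empirical_equals_zero_without_selection(self, rng):
        cohort = rng.normal(size=500)
        assert ks.selection_intensity_empirical(cohort, cohort) == pytest.approx(0.0)

    def test_empirical_truncation_matches_theory(self, rng):
        """Top-10% truncation of 1e5 normal draws gives i close to 1.75."""
        cohort = rng.normal(size=100_000)
        selected = np.sort(cohort)[-10_000:]
        i_hat = ks.selection_intensity_empirical(selected, cohort)
        assert i_hat == pytest.approx(1.755, abs=0.02)

    def test_empirical_hand_case(self):
        # cohort {0, 2}: population sd = 1, so selecting {2} gives exactly 1
        assert ks.selection_intensity_empirical([2.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_empirical_zero_variance_is_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(ks.selection_intensity_empirical([1.0], [1.0, 1.0]))


class TestSchemeConfig:
    def test_reference_and_intervention_levels_valid(self):
        ks.SchemeConfig()  # 2yr / 400 / random / 24
        ks.SchemeConfig(cycle_time=1, num_cross=1000, select_sp="pheno", n_gp=96)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"num_cross": 401},
            {"select_sp": "gebv"},
            {"cycle_time": 0},
            {"horizon": 1},
            {"n_gp": 0},
            {"num_cross": 400, "n_gp": 24, "sp_selected_fraction": 0.01},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            ks.SchemeConfig(**kwargs)


class TestSelectSporophytes:
    def _cohort(self, phenos):
        n = len(phenos)
        return ks.SporophyteCohort(
            haplotypes=np.zeros((n, 2, 4), np.uint8),
            genetic_values=np.zeros(n),
            year=2,
            phenotypes=np.asarray(phenos, dtype=float),
        )

    def test_ten_percent_counts(self, rng):
        """10% selection keeps 40 of 400 and 100 of 1,000 plots."""
        assert select_sporophytes(
            self._cohort(np.arange(400)), "random", 0.10, rng
        ).size == 40
        assert select_sporophytes(
            self._cohort(np.arange(1000)), "random", 0.10, rng
        ).size == 100

    def test_phenotypic_selection_keeps_top(self, rng):
        cohort = self._cohort(np.arange(1, 401))
        sel = select_sporophytes(cohort, "pheno", 0.10, rng)
        assert np.array_equal(np.sort(cohort.phenotypes[sel]), np.arange(361, 401))

    def test_ties_broken_by_id_order(self, rng):
        cohort = self._cohort(np.zeros(10))
        sel = select_sporophytes(cohort, "pheno", 0.5, rng)
        assert np.array_equal(sel, np.arange(5))

    def test_random_selection_reproducible(self):
        cohort = self._cohort(np.arange(100))
        s1 = select_sporophytes(cohort, "random", 0.1, np.random.default_rng(3))
        s2 = select_sporophytes(cohort, "random", 0.1, np.random.default_rng(3))
        assert np.array_equal(s1, s2)

    def test_empty_cohort_raises(self, rng):
        with pytest.raises(SchemeError):
            select_sporophytes(self._cohort([]), "random", 0.1, rng)


class TestProduceGametophytes:
    def test_counts(self, gp_cohort):
        assert len(gp_cohort) == 60 * 8

    def test_homozygous_parent_gives_identical_gametophytes(
        self, small_founders, small_trait, rng
    ):
        n_sites = small_founders.genetic_map.n_sites
        hap = rng.integers(0, 2, n_sites, dtype=np.uint8)
        cohort = ks.SporophyteCohort(
            haplotypes=np.stack([hap, hap])[None],
            genetic_values=np.zeros(1),
            year=2,
        )
        gps = produce_gametophytes(
            cohort, np.array([0]), 20, small_founders.genetic_map, small_trait,
            rng, year=2,
        )
        assert np.all(gps.haplotypes == hap)

    def test_sex_ratio_binomial(self, small_founders, small_trait, rng):
        cohort = ks.SporophyteCohort.from_founders(small_founders, small_trait)
        gps = produce_gametophytes(
            cohort, np.arange(200), 50, small_founders.genetic_map, small_trait,
            rng, year=1,
        )
        n = len(gps)
        n_female = int((gps.sex == 0).sum())
        assert abs(n_female - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_individual_view(self, gp_cohort):
        ind = gp_cohort.individual(3)
        assert ind.sex in ("F", "M")
        assert ind.genetic_value == pytest.approx(gp_cohort.genetic_values[3])


class TestSelectGametophytes:
    @pytest.mark.parametrize(
        "n_gp,expected_fraction",
        [(24, 1 / 2.4), (96, 1 / 9.6)],  # 41.7% and 10.4% of candidates
    )
    def test_selected_fraction(
        self, small_founders, small_trait, n_gp, expected_fraction
    ):
        """Selecting NumCross/2 per sex out of 0.10*NumCross*n_gp candidates
        reproduces the scheme's gametophyte-stage selected proportions."""
        rng = np.random.default_rng(0)
        num_cross = 40
        n_selected_sp = 4
        cohort = ks.SporophyteCohort.from_founders(small_founders, small_trait)
        gps = produce_gametophytes(
            cohort, np.arange(n_selected_sp), n_gp,
            small_founders.genetic_map, small_trait, rng, year=2,
        )
        gps.gebv = rng.normal(size=len(gps))
        f_sel, m_sel = select_gametophytes(gps, None, num_cross)
        assert f_sel.size == m_sel.size == num_cross // 2
        assert (f_sel.size + m_sel.size) / len(gps) == pytest.approx(
            expected_fraction, rel=0.01
        )

    def test_truncation_keeps_highest_gebv_per_sex(self, gp_cohort, rng):
        gp_cohort.gebv = rng.normal(size=len(gp_cohort))
        f_sel, m_sel = select_gametophytes(gp_cohort, None, 20)
        for sel, code in ((f_sel, 0), (m_sel, 1)):
            members = np.nonzero(gp_cohort.sex == code)[0]
            rest = np.setdiff1d(members, sel)
            assert gp_cohort.gebv[sel].min() >= gp_cohort.gebv[rest].max()

    def test_all_equal_gebv_selects_first_ids(self, gp_cohort):
        gp_cohort.gebv = np.zeros(len(gp_cohort))
        f_sel, _ = select_gametophytes(gp_cohort, None, 20)
        females = np.nonzero(gp_cohort.sex == 0)[0]
        assert np.array_equal(f_sel, females[:10])

    def test_sex_shortfall_names_deficient_sex(self, gp_cohort):
        gp_cohort.gebv = np.zeros(len(gp_cohort))
        gp_cohort.sex = np.zeros(len(gp_cohort), np.uint8)  # all female
        with pytest.raises(SchemeError, match="M gametophytes"):
            select_gametophytes(gp_cohort, None, 20)

    def test_missing_model_raises(self, gp_cohort):
        with pytest.raises(SchemeError, match="GEBV"):
            select_gametophytes(gp_cohort, None, 20)


class TestMakeCrosses:
    def test_two_regular_bipartite_structure(self, gp_cohort, small_trait, rng):
        females = np.nonzero(gp_cohort.sex == 0)[0][:100]
        males = np.nonzero(gp_cohort.sex == 1)[0][:100]
        cohort = make_crosses(gp_cohort, females, males, small_trait, rng, year=2)
        assert len(cohort) == 200
        for parents in (cohort.parent_f, cohort.parent_m):
            _, counts = np.unique(parents, return_counts=True)
            assert np.all(counts == 2)

    def test_single_pair_forced_twice(self, gp_cohort, small_trait, rng):
        female = np.nonzero(gp_cohort.sex == 0)[0][:1]
        male = np.nonzero(gp_cohort.sex == 1)[0][:1]
        cohort = make_crosses(gp_cohort, female, male, small_trait, rng, year=2)
        assert len(cohort) == 2
        assert np.array_equal(cohort.haplotypes[0], cohort.haplotypes[1])

    def test_genetic_values_match_direct_recomputation(
        self, gp_cohort, small_trait, rng
    ):
        """Cross values from parental additivity equal the direct QTL sum."""
        females = np.nonzero(gp_cohort.sex == 0)[0][:30]
        males = np.nonzero(gp_cohort.sex == 1)[0][:30]
        cohort = make_crosses(gp_cohort, females, males, small_trait, rng, year=2)
        direct = ks.genetic_value_diploid(cohort.haplotypes, small_trait)
        assert cohort.genetic_values == pytest.approx(direct, abs=1e-4)

    def test_cohort_mean_matches_parent_mean(self, gp_cohort, small_trait, rng):
        females = np.nonzero(gp_cohort.sex == 0)[0][:50]
        males = np.nonzero(gp_cohort.sex == 1)[0][:50]
        cohort = make_crosses(gp_cohort, females, males, small_trait, rng, year=2)
        parent_mean = gp_cohort.genetic_values[np.concatenate([females, males])].mean()
        assert cohort.genetic_values.mean() == pytest.approx(parent_mean, abs=1e-6)

    def test_size_mismatch_raises(self, gp_cohort, small_trait, rng):
        with pytest.raises(SchemeError):
            make_crosses(
                gp_cohort,
                np.nonzero(gp_cohort.sex == 0)[0][:3],
                np.nonzero(gp_cohort.sex == 1)[0][:2],
                small_trait,
                rng,
                year=2,
            )


class TestRunScheme:
    CFG = dict(num_cross=40, n_gp=24)

    def test_cycle_calendar(self, small_founders, small_trait):
        """With a 10-year horizon the 1-year cycle runs 8 post-founder
        selection rounds (new gametophyte cohorts in years 2-9) and the
        2-year cycle runs 4 (years 2, 4, 6, 8)."""
        for cycle_time, expected_years in [
            (1, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]),
            (2, [1, 2, 4, 6, 8, 10]),
        ]:
            recs = ks.run_scheme(
                ks.SchemeConfig(cycle_time=cycle_time, **self.CFG),
                small_founders,
                small_trait,
                np.random.default_rng(0),
                gs_lambda="auto",
            )
            assert [r.year for r in recs] == list(range(1, 11))
            assert [r.year for r in recs if r.new_cohort] == expected_years

    def test_carry_forward_repeats_metrics(self, small_founders, small_trait):
        recs = ks.run_scheme(
            ks.SchemeConfig(cycle_time=2, **self.CFG),
            small_founders,
            small_trait,
            np.random.default_rng(1),
            gs_lambda="auto",
        )
        by_year = {r.year: r for r in recs}
        assert by_year[3].mean_g == by_year[2].mean_g
        assert by_year[9].var_g == by_year[8].var_g

    def test_deterministic_under_seed(self, small_founders, small_trait):
        runs = [
            ks.run_scheme(
                ks.SchemeConfig(**self.CFG),
                small_founders,
                small_trait,
                np.random.default_rng(5),
                gs_lambda="auto",
            )
            for _ in range(2)
        ]
        assert all(
            a.mean_g == b.mean_g and a.var_g == b.var_g and
            (a.accuracy == b.accuracy or (np.isnan(a.accuracy) and np.isnan(b.accuracy)))
            for a, b in zip(*runs)
        )

    def test_null_model_and_random_selection_gain_zero(
        self, small_founders, small_trait
    ):
        """Random sporophyte selection with all marker effects shrunk to
        zero (lambda -> inf) leaves no selection pressure: mean 10-year gain
        across replicates is indistinguishable from zero."""
        gains = []
        for rep in range(20):
            recs = ks.run_scheme(
                ks.SchemeConfig(select_sp="random", **self.CFG),
                small_founders,
                small_trait,
                np.random.default_rng(100 + rep),
                gs_lambda=np.inf,
            )
            gains.append(recs[-1].mean_g - recs[1].mean_g)
        t = np.mean(gains) / (np.std(gains, ddof=1) / np.sqrt(len(gains)))
        assert abs(t) < 4

    def test_directional_selection_gains(self, small_founders, small_trait):
        """Phenotypic + genomic selection at h2 = 0.5 lifts the genetic mean
        by year 10 in nearly every replicate."""
        wins = 0
        for rep in range(20):
            recs = ks.run_scheme(
                ks.SchemeConfig(select_sp="pheno", **self.CFG),
                small_founders,
                small_trait,
                np.random.default_rng(200 + rep),
                gs_lambda="auto",
            )
            wins += recs[-1].mean_g > recs[1].mean_g
        assert wins >= 19

    def test_gain_decomposition_tracks_i_r_sigma(self, small_founders, small_trait):
        """Realized per-cycle gains correlate positively with the breeder's
        equation prediction i * r * sigma_a computed from logged metrics."""
        preds, gains = [], []
        i_gp = ks.selection_intensity_theoretical(1 / 2.4)
        for rep in range(10):
            recs = ks.run_scheme(
                ks.SchemeConfig(cycle_time=1, select_sp="random", **self.CFG),
                small_founders,
                small_trait,
                np.random.default_rng(300 + rep),
                gs_lambda="auto",
            )
            new = [r for r in recs if r.new_cohort and r.year >= 2]
            for a, b in zip(new[:-1], new[1:]):
                gains.append(b.mean_g - a.mean_g)
                preds.append(i_gp * a.accuracy * np.sqrt(max(a.var_g, 0.0)))
        rho = stats.spearmanr(preds, gains).statistic
        assert rho > 0

    def test_pedigree_export(self, small_founders, small_trait):
        recs, pedigree = ks.run_scheme(
            ks.SchemeConfig(cycle_time=2, **self.CFG),
            small_founders,
            small_trait,
            np.random.default_rng(4),
            gs_lambda="auto",
            record_pedigree=True,
        )
        assert len(recs) == 10
        assert set(pedigree.columns) == {
            "year", "child", "parent_f_sporophyte", "parent_m_sporophyte"
        }
        # every evaluated cohort before the last selection is recorded
        assert (pedigree.groupby("year").size() == 40).all()
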