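"""Zygosity qualification, rarity partition and Grubbs outlier exclusion."""

import numpy as np
import pytest
from scipy import stats

from urvburden import Cohort, QCConfig, SiteClass, grubbs_outliers, partition_by_rarity, qualify_genotype
from urvburden.rarity import InsufficientDataError, classify_site, grubbs_pvalue, grubbs_statistic

from conftest import make_individual, make_variant

male = make_individual("M", sex="male")
female = make_individual("F", sex="female")
xxy = make_individual("K", sex="male", karyotype="XXY")


class TestQualifyGenotype:
    @pytest.mark.parametrize(
        "site, genotype, individual, expected",
        [
            # rule 1: autosomal heterozygotes
            (SiteClass.AUTOSOME, "het", male, True),
            (SiteClass.AUTOSOME, "het", female, True),
            (SiteClass.AUTOSOME, "hom", male, False),
            # rule 2: pseudoautosomal heterozygotes
            (SiteClass.PAR, "het", female, True),
            (SiteClass.PAR, "hom", female, False),
            # rule 3: X-non-PAR het in females and 47,XXY
            (SiteClass.X_NONPAR, "het", female, True),
            (SiteClass.X_NONPAR, "het", xxy, True),
            (SiteClass.X_NONPAR, "het", male, False),
            # rule 4: X-non-PAR hemizygotes in (non-XXY) males
            (SiteClass.X_NONPAR, "hom", male, True),
            (SiteClass.X_NONPAR, "hemi", male, True),
            (SiteClass.X_NONPAR, "hom", female, False),
            (SiteClass.X_NONPAR, "hom", xxy, False),
            # rule 5: Y hemizygotes in males and 47,XXY
            (SiteClass.Y, "hom", male, True),
            (SiteClass.Y, "hemi", xxy, True),
            (SiteClass.Y, "het", male, False),
            (SiteClass.Y, "hom", female, False),
        ],
    )
    def test_rules(self, site, genotype, individual, expected):
        assert qualify_genotype(site, genotype, individual) is expected

    def test_unknown_site_class_raises(self):
        from urvburden.rarity import ClassificationError

        with pytest.raises(ClassificationError):
            qualify_genotype("autosome", "het", male)

    def test_site_classification(self):
        assert classify_site("chr7", 100) is SiteClass.AUTOSOME
        assert classify_site("X", 100) is SiteClass.X_NONPAR
        assert classify_site("Y", 100) is SiteClass.Y
        assert classify_site("MT", 100) is None


class TestPartition:
    def _cohort(self, variants):
        inds = [make_individual(f"S{i}", sex="female") for i in range(1, 7)]
        return Cohort(individuals=inds, variants=variants)

    def test_db_present_variant_excluded_even_as_singleton(self):
        v = make_variant(external_db={"exac": True})
        bins = partition_by_rarity(self._cohort([v]))
        assert bins["common_or_excluded"] == [v] and not bins["singleton"]

    def test_panel_free_doubleton(self):
        v = make_variant(carriers=[("S1", "het"), ("S2", "het")])
        bins = partition_by_rarity(self._cohort([v]))
        assert bins["doubleton"] == [v]

    def test_hand_enumerated_bins(self):
        carriers = lambda k: [(f"S{i}", "het") for i in range(1, k + 1)]
        variants = [
            make_variant(pos=1, carriers=carriers(1)),                       # singleton
            make_variant(pos=2, carriers=carriers(1), external_db={"esp": True}),  # excluded
            make_variant(pos=3, carriers=carriers(2)),                       # doubleton
            make_variant(pos=4, carriers=carriers(3)),                       # tripleton
            make_variant(pos=5, carriers=carriers(4)),                       # common
            make_variant(pos=6, carriers=carriers(1), external_db={"tommo": True}),
            make_variant(pos=7, carriers=carriers(2)),
            make_variant(pos=8, carriers=carriers(1)),
            make_variant(pos=9, carriers=carriers(3), external_db={"exac": True}),
            make_variant(chrom="X", pos=10, carriers=[("S1", "hom")]),       # female hom X: 0 qualifying
        ]
        bins = partition_by_rarity(self._cohort(variants))
        assert [v.pos for v in bins["singleton"]] == [1, 8]
        assert [v.pos for v in bins["doubleton"]] == [3, 7]
        assert [v.pos for v in bins["tripleton"]] == [4]
        assert [v.pos for v in bins["common_or_excluded"]] == [2, 5, 6, 9, 10]

    def test_bins_partition_the_input(self, sim300):
        cohort, _ = sim300
        bins = partition_by_rarity(cohort)
        assert sum(len(b) for b in bins.values()) == len(cohort.variants)
        seen = set()
        for b in bins.values():
            for v in b:
                assert id(v) not in seen
                seen.add(id(v))


class TestGrubbs:
    def test_tight_cluster_has_no_outliers(self):
        assert grubbs_outliers([50, 51, 52, 53, 54]) == []

    def test_gross_outlier_excluded_against_t_oracle(self):
        values = [50, 51, 52, 53, 500]
        # independent oracle: critical value from the t distribution
        n = 5
        alpha = 0.001
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        g, idx = grubbs_statistic(np.asarray(values, dtype=float))
        assert idx == 4 and g > g_crit
        assert grubbs_outliers(values, QCConfig(grubbs_alpha=alpha)) == [4]

    def test_pvalue_matches_critical_value_at_alpha(self):
        # at G = G_crit the two-sided P equals alpha by construction
        n, alpha = 30, 0.01
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_pvalue(g_crit, n) == pytest.approx(alpha, rel=1e-9)

    def test_too_few_values_raise(self):
        with pytest.raises(InsufficientDataError):
            grubbs_outliers([1.0, 2.0])

    def test_monte_carlo_false_positive_calibration(self):
        # under normality the per-cohort exclusion count is tiny at alpha=0.001
        rng = np.random.default_rng(0)
        n_excluded = [
            len(grubbs_outliers(rng.normal(54.4, 8.2, size=3000)))
            for _ in range(5)
        ]
        # expected ~ alpha * n per pass; a handful at most, never dozens
        assert max(n_excluded) <= 15
        assert np.mean(n_excluded) <= 8

    def test_exclusion_is_phenotype_blind_and_single_pass_flag(self):
        values = [50.0] * 20 + [500.0, 600.0]
        iterative = grubbs_outliers(values)
        single = grubbs_outliers(values, QCConfig(iterate=False))
        assert set(single) <= set(iterative)
        assert len(single) == 1 and len(iterative) == 2
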