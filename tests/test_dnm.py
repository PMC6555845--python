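"""Damaging DNM rate construction, Poisson tail, enrichment test, inversion."""

import math

import numpy as np
import pytest

from urvburden import GeneInfo, RateScaling, damaging_rate, dnm_enrichment, invert_lambda, poisson_tail
from urvburden.dnm import RateError


def series_tail_oracle(lam, k):
    """P(X >= k) by direct series summation of the complement."""
    return 1.0 - sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(k))


GI = GeneInfo(gene="G", pli=0.99,
              mu={"nonsense": 1e-6, "frameshift": 1e-6, "splice_site": 1e-6,
                  "missense": 1.252e-5, "synonymous": 5e-6})


class TestDamagingRate:
    def test_definition_arithmetic(self):
        mu_null, mu_cd = damaging_rate(GI)
        assert mu_null == pytest.approx(3e-6)
        assert mu_cd == pytest.approx(1.252e-5 * 203 / 1252)
        assert mu_cd == pytest.approx(2.03e-6)

    def test_zero_rates(self):
        gi = GeneInfo(gene="Z", pli=0.0,
                      mu={"nonsense": 0, "frameshift": 0, "splice_site": 0, "missense": 0})
        assert damaging_rate(gi) == (0.0, 0.0)

    def test_identity_scaling(self):
        _, mu_cd = damaging_rate(GI, RateScaling(cd_missense_fraction=1 - 1e-12))
        assert mu_cd == pytest.approx(1.252e-5)

    def test_missing_component_named(self):
        gi = GeneInfo(gene="M", pli=0.5, mu={"nonsense": 1e-6, "missense": 1e-5})
        with pytest.raises(RateError, match="frameshift"):
            damaging_rate(gi)


class TestPoissonTail:
    def test_edge_cases(self):
        assert poisson_tail(0.0, 1) == 0.0
        assert poisson_tail(0.5, 0) == 1.0
        assert poisson_tail(0.0, 0) == 1.0
        with pytest.raises(ValueError):
            poisson_tail(-1.0, 1)

    def test_small_lambda_series(self):
        lam = 0.03
        expected = 1 - math.exp(-lam) * (1 + lam + lam**2 / 2)
        assert poisson_tail(lam, 3) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("lam", [1e-4, 0.01, 0.1, 0.5, 1.0])
    @pytest.mark.parametrize("k", list(range(1, 11)))
    def test_agrees_with_series_oracle(self, lam, k):
        assert poisson_tail(lam, k) == pytest.approx(series_tail_oracle(lam, k),
                                                     abs=1e-12)


class TestInvertLambda:
    def test_round_trip(self):
        p = poisson_tail(0.05, 3)
        assert invert_lambda(p, 3) == pytest.approx(0.05, rel=1e-9)

    def test_series_initialized_bisection_oracle(self):
        # independent oracle: bisection on the series tail
        p_target, k = 2.55e-7, 3
        lo, hi = 1e-6, 1.0
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if series_tail_oracle(mid, k) < p_target:
                lo = mid
            else:
                hi = mid
        assert invert_lambda(p_target, k) == pytest.approx(math.sqrt(lo * hi), rel=1e-6)
        # leading-order check: lambda ~ (6 p)^(1/3)
        assert invert_lambda(p_target, k) == pytest.approx((6 * p_target) ** (1 / 3),
                                                           rel=5e-3)

    def test_monotone_in_p(self):
        lams = [invert_lambda(p, 2) for p in (1e-8, 1e-6, 1e-4, 1e-2)]
        assert lams == sorted(lams)

    def test_domain(self):
        with pytest.raises(ValueError):
            invert_lambda(0.0, 3)
        with pytest.raises(ValueError):
            invert_lambda(0.5, 0)


class TestEnrichment:
    def test_zero_observed_is_null(self):
        res = dnm_enrichment(GI, k_observed=0, n_trios=237,
                             n_testable_genes=10_800, n_subtypes=8)
        assert res.p == 1.0
        assert res.p_gene_corrected == 1.0 and res.p_subtype_corrected == 1.0

    def test_lambda_construction(self):
        res = dnm_enrichment(GI, k_observed=2, n_trios=100,
                             n_testable_genes=100, n_subtypes=8)
        assert res.lambda_ == pytest.approx((3e-6 + 2.03e-6) * 200)

    def test_subtype_correction_multiplies_by_count(self):
        lam = invert_lambda(2.55e-7, 3)
        res = dnm_enrichment(GI, k_observed=3, n_trios=237, n_testable_genes=10_800,
                             n_subtypes=8, lambda_override=lam)
        assert res.p == pytest.approx(2.55e-7, rel=1e-6)
        assert res.p_subtype_corrected == pytest.approx(2.04e-6, rel=1e-3)

    def test_corrections_capped_at_one(self):
        res = dnm_enrichment(GI, k_observed=1, n_trios=627,
                             n_testable_genes=10_800, n_subtypes=8)
        assert res.p_gene_corrected <= 1.0

    def test_tail_scales_cubically_in_trios_for_k3(self):
        lam237 = invert_lambda(2.55e-7, 3)
        p237 = poisson_tail(lam237, 3)
        p627 = poisson_tail(lam237 * 627 / 237, 3)
        assert p627 / p237 == pytest.approx((627 / 237) ** 3, rel=0.05)

    def test_planted_enrichment_recovered_in_mutable_target_gene(self):
        # a 100-gene panel whose target gene sits at the extreme of the
        # per-gene mutability distribution (per-haploid damaging rate ~3e-4)
        from urvburden.simulate import simulate_trio_dnms

        genes = {
            f"g{i:03d}": GeneInfo(
                gene=f"g{i:03d}", pli=0.5,
                mu={"nonsense": 9e-7, "frameshift": 7e-7, "splice_site": 4.5e-7,
                    "missense": 1.1e-5, "synonymous": 5e-6})
            for i in range(99)
        }
        genes["target"] = GeneInfo(
            gene="target", pli=1.0,
            mu={"nonsense": 1.0e-4, "frameshift": 5.0e-5, "splice_site": 2.5e-5,
                "missense": 7.5e-4, "synonymous": 3e-4})
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            counts = simulate_trio_dnms(genes, 237, enriched_genes=["target"],
                                        fold=50, seed=seed)
            ps = {g: dnm_enrichment(genes[g], int(k), 237, 1, 1).p
                  for g, k in counts.items() if k > 0}
            if ps and min(ps, key=ps.get) == "target":
                wins += 1
        assert wins / n_seeds >= 0.95

    def test_type_one_error_is_conservative_under_simulation(self):
        # many simulated gene-tests at the exome-wide level
        rng = np.random.default_rng(12)
        lam = 0.004
        k = rng.poisson(lam, size=2_000_000)
        alpha = 2.5e-6
        # smallest k with poisson_tail(lam, k) <= alpha
        k_crit = 1
        while poisson_tail(lam, k_crit) > alpha:
            k_crit += 1
        rejections = np.mean(k >= k_crit)
        assert rejections <= alpha
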