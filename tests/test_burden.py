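"""Per-individual counting, logistic burden fits, separation handling,
multiplicity adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urvburden import (
    Cohort,
    GeneSet,
    adjust_pvalues,
    count_urvs,
    fit_burden,
    handle_separation,
)
from urvburden.burden import SeparationError
from urvburden.classify import FunctionalClass

from conftest import make_individual, make_variant


def _classified(v, leaf):
    v.functional_class = leaf
    return v


class TestCountUrvs:
    def _cohort(self):
        inds = [make_individual(f"S{i}", status="case" if i == 1 else "control")
                for i in range(1, 4)]
        variants = [
            _classified(make_variant(pos=1, gene="GA"), FunctionalClass.NULL),
            _classified(make_variant(pos=2, gene="GA"), FunctionalClass.NULL),
            _classified(make_variant(pos=3, gene="GB"), FunctionalClass.CD_MISSENSE),
            _classified(make_variant(pos=4, gene="GB", carriers=[("S2", "het")]),
                        FunctionalClass.OTHER_MODERATE),
        ]
        return Cohort(individuals=inds, variants=variants)

    def test_durv_count_is_additive_over_null_and_cd(self):
        counts = count_urvs(self._cohort(), "durv")
        assert counts["S1"] == 3 and counts["S2"] == 0

    def test_gene_set_restriction_zeroes_outside_genes(self):
        with pytest.warns(UserWarning, match="all zeros"):
            counts = count_urvs(self._cohort(), "null",
                                gene_set=GeneSet(name="s", genes={"GB"}))
        assert counts["S1"] == 0

    def test_empty_intersection_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            counts = count_urvs(self._cohort(), "sr_synonymous")
        assert (counts == 0).all()

    def test_matches_per_variant_loop_oracle(self, sim300):
        cohort, _ = sim300
        counts = count_urvs(cohort, "durv")
        oracle = dict.fromkeys(cohort.individual_ids, 0)
        for v in cohort.variants:
            if v.functional_class in (FunctionalClass.NULL, FunctionalClass.CD_MISSENSE):
                for ind_id, _ in v.carriers:
                    oracle[ind_id] += 1
        assert counts.to_dict() == oracle


def _synthetic_counts(rng, n_case, n_control, beta=0.0, mean=5.0):
    inds = []
    counts = {}
    for i in range(n_case + n_control):
        ind_id = f"I{i:04d}"
        c = rng.poisson(mean)
        counts[ind_id] = float(c)
        inds.append(make_individual(
            ind_id, status="control", sex="male" if rng.random() < 0.5 else "female",
            callable_fraction=float(rng.uniform(0.95, 0.99)),
            pcs=tuple(rng.standard_normal(10)),
        ))
    # assign status by the logistic model so beta is the true log-OR
    eta = np.array([beta * counts[ind.id] for ind in inds])
    eta += np.log(n_case / n_control) - beta * mean
    p = 1 / (1 + np.exp(-eta))
    for ind, pi in zip(inds, p):
        ind.status = "case" if rng.random() < pi else "control"
    # ensure both groups present
    if not any(i.is_case for i in inds):
        inds[0].status = "case"
    if all(i.is_case for i in inds):
        inds[0].status = "control"
    return pd.Series(counts), inds


class TestFitBurden:
    def test_two_by_two_closed_form_equivalence(self):
        # binary count, no covariates: beta equals the log cross-product ratio
        rng = np.random.default_rng(5)
        inds, counts = [], {}
        table = {("case", 1): 30, ("case", 0): 70, ("control", 1): 40, ("control", 0): 160}
        i = 0
        for (status, x), k in table.items():
            for _ in range(k):
                ind_id = f"I{i:04d}"
                inds.append(make_individual(ind_id, status=status))
                counts[ind_id] = float(x)
                i += 1
        res = fit_burden(pd.Series(counts), inds, include_covariates=False)
        expected = np.log((30 * 160) / (70 * 40))
        assert res.beta == pytest.approx(expected, abs=1e-6)

    def test_null_model_gives_or_near_one(self):
        rng = np.random.default_rng(1)
        counts, inds = _synthetic_counts(rng, 150, 450, beta=0.0)
        res = fit_burden(counts, inds)
        assert res.ci95[0] < 1.0 < res.ci95[1]
        assert res.converged

    def test_parameter_recovery_at_or_1_3(self):
        rng = np.random.default_rng(2)
        betas = []
        for _ in range(30):
            counts, inds = _synthetic_counts(rng, 250, 750, beta=np.log(1.3))
            betas.append(fit_burden(counts, inds).beta)
        assert np.mean(betas) == pytest.approx(np.log(1.3), abs=0.03)

    def test_count_shift_is_absorbed_by_the_intercept(self):
        rng = np.random.default_rng(3)
        counts, inds = _synthetic_counts(rng, 100, 300, beta=np.log(1.2))
        a = fit_burden(counts, inds)
        b = fit_burden(counts + 5.0, inds)
        assert a.beta == pytest.approx(b.beta, abs=1e-6)
        assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_one_class_only_raises(self):
        counts = pd.Series({"A": 1.0, "B": 2.0})
        inds = [make_individual("A", status="case"), make_individual("B", status="case")]
        with pytest.raises(ValueError):
            fit_burden(counts, inds)


class TestSeparation:
    def _separated(self):
        # all carriers are cases, but one case is a non-carrier so the
        # pseudo-count refit has no empty cell left
        inds = [make_individual(f"C{i}", status="case") for i in range(6)]
        inds += [make_individual(f"K{i}", status="control") for i in range(12)]
        case_counts = [2.0, 1.0, 1.0, 1.0, 1.0, 0.0]
        counts = pd.Series({
            ind.id: (case_counts[i] if i < 6 else 0.0)
            for i, ind in enumerate(inds)
        })
        return counts, inds

    def test_pseudo_count_refit_flags_upper_bound(self):
        counts, inds = self._separated()
        res = handle_separation(counts, inds, include_covariates=False)
        assert res.separation_flag and res.p_is_upper_bound
        assert 0 < res.p <= 1

    def test_pseudo_count_goes_to_first_control_lexicographically(self):
        counts, inds = self._separated()
        res = handle_separation(counts, inds, include_covariates=False)
        adjusted = counts.copy()
        adjusted["K0"] += 1
        direct = fit_burden(adjusted, inds, include_covariates=False)
        assert res.beta == pytest.approx(direct.beta, abs=1e-9)
        assert res.p == pytest.approx(direct.p, rel=1e-9)

    def test_no_separation_is_a_pass_through(self):
        rng = np.random.default_rng(4)
        counts, inds = _synthetic_counts(rng, 60, 180, beta=0.2)
        res = handle_separation(counts, inds)
        direct = fit_burden(counts, inds)
        assert not res.separation_flag
        assert res.beta == direct.beta

    def test_no_controls_is_unrecoverable(self):
        inds = [make_individual(f"C{i}", status="case") for i in range(4)]
        counts = pd.Series({ind.id: float(i < 2) for i, ind in enumerate(inds)})
        counts["C0"] = 1.0
        with pytest.raises((SeparationError, ValueError)):
            handle_separation(counts, inds)


class TestAdjustPvalues:
    def test_printed_bonferroni_example(self):
        # one significant P among 66 hypotheses
        ps = [0.000215] + [0.5] * 65
        adj = adjust_pvalues(ps, "bonferroni")
        assert round(adj[0], 4) == 0.0142

    def test_bh_step_up_hand_example(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_test_is_identity(self):
        assert adjust_pvalues([0.37], "bonferroni")[0] == pytest.approx(0.37)
        assert adjust_pvalues([0.37], "bh")[0] == pytest.approx(0.37)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5], "bonferroni")
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "bh")

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_ordering_and_naive_oracles(self, ps):
        bonf = adjust_pvalues(ps, "bonferroni")
        bh = adjust_pvalues(ps, "bh")
        p = np.asarray(ps)
        m = len(ps)
        assert np.all(bonf >= bh - 1e-12) and np.all(bh >= p - 1e-12)
        # naive oracles
        assert np.allclose(bonf, np.minimum(1.0, p * m))
        order = np.argsort(p)
        naive = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            naive[i] = running
        assert np.allclose(bh, naive)
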