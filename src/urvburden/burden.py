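"""Covariate-adjusted logistic-regression burden tests.

For each variant class (optionally restricted to a gene set and a case
subset) the per-individual count of qualifying ultra-rare variants is
regressed on case/control status together with sex, the proportion of
callable loci and the first ten principal components. The reported odds
ratio is per additional variant; inference is the Wald z-test on the
count coefficient.

Complete separation (all carriers in one outcome class) is resolved by
the pseudo-count rule: one variant is added to the count of the first
control in lexicographic id order, the model is refit, and the P value is
reported as an upper bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .classify import resolve_class_group
from .cohort import Cohort, GeneSet, IndividualRecord

__all__ = [
    "BurdenResult",
    "AnalysisManifest",
    "SeparationError",
    "count_urvs",
    "fit_burden",
    "handle_separation",
    "adjust_pvalues",
]


class SeparationError(RuntimeError):
    """Complete separation that cannot be resolved (no control group)."""


@dataclass
class BurdenResult:
    """Result of one covariate-adjusted burden regression."""

    variant_class: str = ""
    gene_set: str = ""
    n_variants: int = 0
    beta: float = np.nan
    or_: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    p: float = np.nan
    converged: bool = True
    separation_flag: bool = False
    p_is_upper_bound: bool = False
    p_bonferroni: Optional[float] = None
    p_bh: Optional[float] = None

    def __str__(self) -> str:
        p = f"P < {self.p:.3g}" if self.p_is_upper_bound else f"P = {self.p:.3g}"
        return (
            f"{self.variant_class or 'burden'}"
            f"{' in ' + self.gene_set if self.gene_set else ''}: "
            f"OR = {self.or_:.3f} (95% CI {self.ci95[0]:.3f}-{self.ci95[1]:.3f}), {p}"
        )


@dataclass
class AnalysisManifest:
    """The list of hypotheses tested, fixing m for multiplicity correction."""

    tests: list = field(default_factory=list)  # (test id, class, gene set, case subset)

    @property
    def m(self) -> int:
        return len(self.tests)


def count_urvs(
    cohort: Cohort,
    variant_class="durv",
    gene_set: Optional[GeneSet] = None,
    variants: Optional[Iterable] = None,
    exclude_individuals: Iterable[str] = (),
    include_individuals: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Per-individual count of classified variants in a class (and gene set).

    ``variants`` restricts the counted pool (e.g. the singleton bin from
    the rarity partition); by default all cohort variants are counted.
    Each qualifying carrier entry contributes one.
    """
    leaves = resolve_class_group(variant_class)
    excluded = set(exclude_individuals)
    if include_individuals is not None:
        included = [i for i in include_individuals if i not in excluded]
    else:
        included = [i for i in cohort.individual_ids if i not in excluded]
    counts = dict.fromkeys(included, 0)
    pool = cohort.variants if variants is None else variants
    n_counted = 0
    for v in pool:
        if v.functional_class not in leaves:
            continue
        if gene_set is not None and v.gene not in gene_set:
            continue
        n_counted += 1
        for ind_id, _ in v.carriers:
            if ind_id in counts:
                counts[ind_id] += 1
    if n_counted == 0:
        warnings.warn(
            f"no variants of class {variant_class!r}"
            + (f" in gene set {gene_set.name!r}" if gene_set is not None else "")
            + "; count vector is all zeros",
            stacklevel=2,
        )
    return pd.Series(counts, name="count", dtype=float)


def _design_matrix(counts: pd.Series, individuals: Sequence[IndividualRecord],
                   include_covariates: bool = True):
    by_id = {ind.id: ind for ind in individuals}
    rows, y = [], []
    for ind_id, c in counts.items():
        ind = by_id[ind_id]
        if include_covariates:
            rows.append(
                [c, 1.0 if ind.sex == "male" else 0.0, ind.callable_fraction, *ind.pcs]
            )
        else:
            rows.append([c])
        y.append(1.0 if ind.is_case else 0.0)
    cols = ["count"]
    if include_covariates:
        cols += ["sex", "callable_fraction"] + [f"pc{i}" for i in range(1, 11)]
    X = pd.DataFrame(rows, columns=cols, index=counts.index)
    return sm.add_constant(X), np.asarray(y)


def _is_separated(counts: pd.Series, individuals: Sequence[IndividualRecord]) -> bool:
    by_id = {ind.id: ind for ind in individuals}
    statuses = {by_id[i].status for i, c in counts.items() if c > 0}
    return len(statuses) == 1 and any(c > 0 for c in counts)


def fit_burden(
    counts: pd.Series,
    individuals: Sequence[IndividualRecord],
    variant_class: str = "",
    gene_set: str = "",
    maxiter: int = 100,
    tol: float = 1e-8,
    include_covariates: bool = True,
) -> BurdenResult:
    """Maximum-likelihood logistic fit of status on count + 12 covariates.

    ``include_covariates=False`` drops the covariate block (count-only
    model, useful for closed-form cross-checks). Non-convergence is
    flagged on the result rather than raised. Complete separation on the
    count column should be routed through :func:`handle_separation`.
    """
    X, y = _design_matrix(counts, individuals, include_covariates)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = model.fit(disp=0, maxiter=maxiter, method="bfgs")
            converged = bool(res.mle_retvals.get("converged", False))
    beta = float(res.params["count"])
    se = float(res.bse["count"])
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return BurdenResult(
        variant_class=variant_class,
        gene_set=gene_set,
        n_variants=int(counts.sum()),
        beta=beta,
        or_=float(np.exp(beta)),
        ci95=ci,
        p=float(res.pvalues["count"]),
        converged=converged,
    )


def handle_separation(
    counts: pd.Series,
    individuals: Sequence[IndividualRecord],
    **fit_kwargs,
) -> BurdenResult:
    """Burden fit with the pseudo-count fix for complete separation.

    If every carrier shares one outcome class, the count of the first
    control (lexicographic id order) is incremented by one, the model is
    refit, and the P value is flagged as an upper bound. Without
    separation this is a plain pass-through to :func:`fit_burden`.
    """
    if not _is_separated(counts, individuals):
        return fit_burden(counts, individuals, **fit_kwargs)
    by_id = {ind.id: ind for ind in individuals}
    controls = sorted(i for i in counts.index if not by_id[i].is_case)
    if not controls:
        raise SeparationError("complete separation and no control group to augment")
    adjusted = counts.copy()
    adjusted[controls[0]] += 1
    result = fit_burden(adjusted, individuals, **fit_kwargs)
    result.separation_flag = True
    result.p_is_upper_bound = True
    return result


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m*p)) or ``bh``
    (Benjamini-Hochberg step-up with monotonicity enforcement)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("all P values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}; use 'bonferroni' or 'bh'")
    return multipletests(p, method=key)[1]
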