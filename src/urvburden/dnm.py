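"""Per-gene de novo mutation (DNM) enrichment under a mutation-rate model.

For a gene with per-haploid consequence-specific mutation rates, the
damaging DNM rate combines the null rate (nonsense + frameshift +
splice-site) with the consensus-damaging missense rate, the latter
obtained by scaling the total missense rate by the fraction of missense
DNMs that are consensus-damaging in unaffected-sibling control trios
(203/1252). The expected damaging DNM count over a cohort of trios is

    lambda = (mu_null + mu_cd_missense) * 2 * n_trios

and the test statistic is the Poisson upper tail P(X >= k) at the
observed damaging DNM count k, Bonferroni-corrected either by the number
of testable genes or by the number of disease subtypes analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import optimize, stats

from .cohort import GeneInfo

__all__ = [
    "RateScaling",
    "DnmTestResult",
    "RateError",
    "damaging_rate",
    "poisson_tail",
    "dnm_enrichment",
    "invert_lambda",
]


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class RateScaling:
    """Fraction of missense DNMs that are consensus-damaging (control trios)."""

    cd_missense_fraction: float = 203 / 1252

    def __post_init__(self):
        if not 0.0 < self.cd_missense_fraction < 1.0:
            raise ValueError("cd_missense_fraction must be in (0, 1)")


@dataclass
class DnmTestResult:
    gene: str
    n_trios: int
    mu_null: float
    mu_cd_missense: float
    lambda_: float
    k_observed: int
    p: float
    p_gene_corrected: float
    p_subtype_corrected: float

    def __str__(self) -> str:
        return (
            f"{self.gene}: {self.k_observed} damaging DNMs observed, "
            f"lambda = {self.lambda_:.4g} over {self.n_trios} trios, "
            f"P = {self.p:.3g} (gene-corrected {self.p_gene_corrected:.3g}, "
            f"subtype-corrected {self.p_subtype_corrected:.3g})"
        )


def damaging_rate(gene_info: GeneInfo, scaling: RateScaling = RateScaling()) -> tuple:
    """(mu_null, mu_cd_missense) for one gene.

    mu_null = mu_nonsense + mu_frameshift + mu_splice_site;
    mu_cd_missense = mu_missense * cd_missense_fraction.
    """
    for component in ("nonsense", "frameshift", "splice_site", "missense"):
        if component not in gene_info.mu:
            raise RateError(f"{gene_info.gene}: missing mutation-rate component {component!r}")
    mu = gene_info.mu
    mu_null = mu["nonsense"] + mu["frameshift"] + mu["splice_site"]
    return float(mu_null), float(mu["missense"] * scaling.cd_missense_fraction)


def poisson_tail(lambda_: float, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Poisson(lambda)."""
    if lambda_ < 0 or k < 0:
        raise ValueError("lambda and k must be nonnegative")
    k = int(k)
    if k == 0:
        return 1.0
    if lambda_ == 0.0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lambda_))


def dnm_enrichment(
    gene_info: GeneInfo,
    k_observed: int,
    n_trios: int,
    n_testable_genes: int,
    n_subtypes: int,
    scaling: RateScaling = RateScaling(),
    lambda_override: Optional[float] = None,
) -> DnmTestResult:
    """Full per-gene damaging-DNM enrichment test with both corrections.

    ``lambda_override`` substitutes a directly supplied expected count
    (e.g. one recovered by :func:`invert_lambda`) for the rate-table
    construction.
    """
    if n_trios < 0 or n_testable_genes < 1 or n_subtypes < 1:
        raise ValueError("n_trios must be >= 0 and correction counts >= 1")
    if lambda_override is not None:
        mu_null = mu_cd = float("nan")
        lam = float(lambda_override)
    else:
        mu_null, mu_cd = damaging_rate(gene_info, scaling)
        lam = (mu_null + mu_cd) * 2 * n_trios
    p = poisson_tail(lam, k_observed)
    return DnmTestResult(
        gene=gene_info.gene,
        n_trios=n_trios,
        mu_null=mu_null,
        mu_cd_missense=mu_cd,
        lambda_=lam,
        k_observed=int(k_observed),
        p=p,
        p_gene_corrected=min(1.0, p * n_testable_genes),
        p_subtype_corrected=min(1.0, p * n_subtypes),
    )


def invert_lambda(p_target: float, k: int, rtol: float = 1e-10) -> float:
    """Solve P(X >= k; lambda) = p_target for lambda by bracketed rooting.

    Initialized from the leading series term lambda ~ (k! * p)^(1/k) and
    refined by Brent's method on a widened bracket.
    """
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    lam0 = float((math.factorial(k) * p_target) ** (1.0 / k))
    lo, hi = lam0 / 100.0, max(lam0 * 100.0, 1.0)
    f = lambda lam: poisson_tail(lam, k) - p_target
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise ArithmeticError("failed to bracket lambda from above")
    while f(lo) > 0:
        lo /= 10.0
        if lo < 1e-300:
            raise ArithmeticError("failed to bracket lambda from below")
    return float(optimize.brentq(f, lo, hi, rtol=rtol, xtol=1e-300))
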