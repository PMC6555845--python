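"""Gene-based collapsing burden test and permutation overlap test.

The collapsing test compares, per gene, the proportions of cases and
controls carrying one or more qualifying (damaging ultra-rare) variant,
by two-tailed Fisher's exact test. Exome-wide significance uses
P < 0.05/20,000 = 2.5e-6; the nominal band is 2.5e-6 <= P < 0.05.

The overlap test shuffles case/control labels (preserving group sizes),
re-runs the gene scan, and records the fraction of nominally significant
genes falling in a reference gene set; the empirical P is the fraction of
permutations with an overlap fraction at least the observed one, reported
as "< 1/iterations" when no permutation reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .classify import resolve_class_group
from .cohort import Cohort, GeneSet

__all__ = [
    "EXOME_WIDE_ALPHA",
    "GeneBurdenResult",
    "PermutationResult",
    "fisher_two_tailed",
    "gene_burden_scan",
    "overlap_fraction",
    "overlap_permutation",
]

#: Exome-wide significance threshold, 0.05 over ~20,000 protein-coding genes.
EXOME_WIDE_ALPHA = 0.05 / 20_000


@dataclass
class GeneBurdenResult:
    """One gene's 2x2 carrier table and Fisher test."""

    gene: str
    case_carriers: int
    control_carriers: int
    n_case: int
    n_control: int
    p: float

    def __post_init__(self):
        if self.case_carriers > self.n_case or self.control_carriers > self.n_control:
            raise ValueError(f"{self.gene}: carrier counts exceed group sizes")

    @property
    def or_(self) -> float:
        """Cross-product odds ratio with 0.5 continuity on zero cells."""
        a, b = self.case_carriers, self.n_case - self.case_carriers
        c, d = self.control_carriers, self.n_control - self.control_carriers
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)

    @property
    def exome_wide(self) -> bool:
        return self.p < EXOME_WIDE_ALPHA

    @property
    def nominal(self) -> bool:
        return EXOME_WIDE_ALPHA <= self.p < 0.05


@dataclass
class PermutationResult:
    """Label-shuffling overlap test summary."""

    observed_overlap_fraction: float
    null_fractions: list = field(default_factory=list)
    iterations: int = 0
    seed: Optional[int] = None

    @property
    def empirical_p(self) -> float:
        exceed = sum(1 for f in self.null_fractions
                     if f >= self.observed_overlap_fraction)
        return exceed / self.iterations

    @property
    def p_string(self) -> str:
        if self.empirical_p == 0.0:
            return f"P < {1 / self.iterations:g}"
        return f"P = {self.empirical_p:g}"


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact P for the table [[a, b], [c, d]].

    Two-sidedness by the usual rule: sum the hypergeometric probabilities
    of all tables with the same margins whose probability does not exceed
    the observed table's. An all-zero table returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


class _CarrierMatrix:
    """Per-gene carrier index lists over a fixed individual ordering."""

    def __init__(self, cohort: Cohort, subset_ids, variant_class, excluded_genes,
                 exclude_individuals):
        leaves = resolve_class_group(variant_class)
        excluded_genes = frozenset(excluded_genes or ())
        excluded_inds = set(exclude_individuals or ())

        if subset_ids is not None:
            subset = set(subset_ids)
            included = [
                ind for ind in cohort.individuals
                if ind.id not in excluded_inds and (not ind.is_case or ind.id in subset)
            ]
        else:
            included = [ind for ind in cohort.individuals if ind.id not in excluded_inds]
        self.ids = [ind.id for ind in included]
        self.labels = np.array([ind.is_case for ind in included], dtype=bool)
        pos = {ind_id: i for i, ind_id in enumerate(self.ids)}
        self.n_case = int(self.labels.sum())
        self.n_control = len(self.ids) - self.n_case

        carriers: dict = {}
        for v in cohort.variants:
            if v.functional_class not in leaves or v.gene in excluded_genes:
                continue
            for ind_id, _ in v.carriers:
                i = pos.get(ind_id)
                if i is not None:
                    carriers.setdefault(v.gene, set()).add(i)
        self.gene_carriers = {
            g: np.fromiter(sorted(s), dtype=np.intp) for g, s in carriers.items()
        }

    def scan(self, labels: np.ndarray, cache: dict) -> list:
        out = []
        for gene, idx in self.gene_carriers.items():
            a = int(labels[idx].sum())
            total = len(idx)
            key = (a, total)
            p = cache.get(key)
            if p is None:
                p = fisher_two_tailed(
                    a, self.n_case - a, total - a, self.n_control - (total - a)
                )
                cache[key] = p
            out.append((gene, a, total - a, p))
        return out


def gene_burden_scan(
    cohort: Cohort,
    subset_ids: Optional[Iterable[str]] = None,
    variant_class="durv",
    excluded_genes: Optional[Iterable[str]] = None,
    exclude_individuals: Optional[Iterable[str]] = None,
) -> list:
    """Collapsing test for every gene with at least one qualifying carrier.

    ``subset_ids`` restricts the case group (controls are always kept);
    ``excluded_genes`` drops genes from the scan entirely. Requires
    classified variants.
    """
    m = _CarrierMatrix(cohort, subset_ids, variant_class, excluded_genes,
                       exclude_individuals)
    cache: dict = {}
    return [
        GeneBurdenResult(gene=g, case_carriers=a, control_carriers=c,
                         n_case=m.n_case, n_control=m.n_control, p=p)
        for g, a, c, p in sorted(m.scan(m.labels, cache))
    ]


def overlap_fraction(results: Sequence[GeneBurdenResult], reference_set: GeneSet) -> float:
    """Fraction of nominally significant genes lying in the reference set.

    Nominal means 2.5e-6 <= P < 0.05. Returns 0.0 when no gene is
    nominally significant.
    """
    nominal = [r.gene for r in results if r.nominal]
    if not nominal:
        return 0.0
    return sum(1 for g in nominal if g in reference_set) / len(nominal)


def _nominal_fraction(rows: list, reference: frozenset) -> Optional[float]:
    nominal = [g for g, a, c, p in rows if EXOME_WIDE_ALPHA <= p < 0.05]
    if not nominal:
        return None
    return sum(1 for g in nominal if g in reference) / len(nominal)


def overlap_permutation(
    cohort: Cohort,
    reference_set: GeneSet,
    iterations: int = 10_000,
    seed: int = 0,
    subset_ids: Optional[Iterable[str]] = None,
    variant_class="durv",
    excluded_genes: Optional[Iterable[str]] = None,
    exclude_individuals: Optional[Iterable[str]] = None,
) -> PermutationResult:
    """Empirical overlap test between nominal genes and a reference set.

    Each iteration permutes case/control labels with an independent
    counter-derived stream off one master seed, re-runs the collapsing
    scan, and records the overlap fraction among nominally significant
    genes (iterations yielding no nominal gene contribute fraction 0).
    Same seed, same result.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    m = _CarrierMatrix(cohort, subset_ids, variant_class, excluded_genes,
                       exclude_individuals)
    cache: dict = {}
    observed = _nominal_fraction(m.scan(m.labels, cache), reference_set.genes)
    observed = 0.0 if observed is None else observed

    null_fractions = []
    master = np.random.SeedSequence(seed)
    for child in master.spawn(iterations):
        rng = np.random.default_rng(child)
        null = _nominal_fraction(
            m.scan(rng.permutation(m.labels), cache), reference_set.genes
        )
        null_fractions.append(0.0 if null is None else null)
    return PermutationResult(
        observed_overlap_fraction=observed,
        null_fractions=null_fractions,
        iterations=iterations,
        seed=seed,
    )
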