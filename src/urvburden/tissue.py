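"""Tissue-expression gene-set burden scan and brain-vs-other contrast.

Per tissue, a gene set of moderately-to-highly expressed genes
(TPM strictly > threshold) is formed from an expression matrix, the
covariate-adjusted burden regression is run on damaging variant counts
restricted to that set, and tissues are ranked by a four-tier
directional order: enrichment (OR > 1) sorted by ascending P first, then
depletion (OR < 1) sorted by descending P. Brain tissues' ranks are
compared with the remaining tissues' by a two-tailed Wilcoxon rank-sum
test (exact for small groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .burden import BurdenResult, count_urvs, fit_burden
from .cohort import Cohort, GeneSet

__all__ = [
    "TissueResult",
    "tpm_gene_sets",
    "tissue_scan",
    "directional_sort",
    "brain_vs_other",
]


@dataclass
class TissueResult:
    tissue: str
    gene_set_size: int
    burden: BurdenResult
    rank: Optional[int] = None

    @property
    def direction(self) -> str:
        return "enriched" if self.burden.or_ >= 1.0 else "depleted"


def tpm_gene_sets(matrix: pd.DataFrame, threshold: float = 10.0) -> dict:
    """Per-tissue gene sets of genes with TPM strictly above ``threshold``.

    ``matrix`` is genes x tissues (TPM, nonnegative).
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    if (matrix.values < 0).any():
        raise ValueError("TPM values must be nonnegative")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sets = {}
    for tissue in matrix.columns:
        genes = matrix.index[matrix[tissue] > threshold]
        if len(genes):
            sets[tissue] = GeneSet(name=str(tissue), genes=frozenset(genes))
    return sets


def tissue_scan(
    cohort: Cohort,
    expression: pd.DataFrame,
    case_subset: Optional[Iterable[str]] = None,
    variant_class="durv",
    threshold: float = 10.0,
    excluded_genes: Iterable[str] = (),
    exclude_individuals: Iterable[str] = (),
) -> list:
    """Burden regression per tissue gene set; same covariates as the main scan.

    ``case_subset`` restricts the case group (controls always kept);
    ``excluded_genes`` (e.g. the known disease genes) are removed from
    every tissue set.
    """
    excluded_genes = frozenset(excluded_genes)
    include = None
    if case_subset is not None:
        subset = set(case_subset)
        include = [
            ind.id for ind in cohort.individuals
            if (not ind.is_case) or ind.id in subset
        ]
    results = []
    for tissue, gene_set in tpm_gene_sets(expression, threshold).items():
        genes = gene_set.genes - excluded_genes
        if not genes:
            continue
        restricted = GeneSet(name=gene_set.name, genes=genes)
        counts = count_urvs(
            cohort, variant_class, gene_set=restricted,
            exclude_individuals=exclude_individuals,
            include_individuals=include,
        )
        burden = fit_burden(counts, cohort.individuals,
                            variant_class=str(variant_class), gene_set=str(tissue))
        results.append(TissueResult(tissue=str(tissue),
                                    gene_set_size=len(genes), burden=burden))
    return results


def directional_sort(results: Sequence[TissueResult]) -> list:
    """Rank tissues: enriched (OR >= 1) by ascending P, then depleted by
    descending P; OR exactly 1 sits at the end of the enriched block; ties
    broken by tissue name. Returns a new list with ranks 1..n assigned."""
    def key(r: TissueResult):
        if r.burden.or_ > 1.0:
            return (0, r.burden.p, r.tissue)
        if r.burden.or_ == 1.0:
            return (1, r.burden.p, r.tissue)
        return (2, -r.burden.p, r.tissue)

    ranked = [
        TissueResult(tissue=r.tissue, gene_set_size=r.gene_set_size,
                     burden=r.burden, rank=i)
        for i, r in enumerate(sorted(results, key=key), start=1)
    ]
    return ranked


def brain_vs_other(ranked: Sequence[TissueResult], brain_labels: Iterable[str]) -> float:
    """Two-tailed Wilcoxon rank-sum P comparing brain vs other tissue ranks.

    Exact distribution when both groups have <= 25 members, normal
    approximation with continuity correction otherwise.
    """
    brain = frozenset(brain_labels)
    ranks_brain = [r.rank for r in ranked if r.tissue in brain]
    ranks_other = [r.rank for r in ranked if r.tissue not in brain]
    if not ranks_brain or not ranks_other:
        raise ValueError("both the brain and the other tissue group must be non-empty")
    method = "exact" if max(len(ranks_brain), len(ranks_other)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(ranks_brain, ranks_other, alternative="two-sided",
                             method=method, use_continuity=True)
    return float(res.pvalue)
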