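"""Rarity partitioning and per-individual count quality control.

Variants are first screened against external population panels (any
variant present in a selected panel is dropped), then binned by the
number of qualifying carrier alleles in the full pre-QC cohort:
singletons (1), doubletons (2), tripletons (3), everything else common.
Zygosity qualification follows the five per-chromosome rules: autosomal
heterozygotes, pseudoautosomal heterozygotes, X-non-PAR heterozygotes in
females and 47,XXY individuals, X-non-PAR homozygotes in males
(hemizygous), and Y homozygotes in males and 47,XXY (hemizygous).

Individuals with exceptionally small or large coding URV counts are
removed by an iterative two-sided Smirnov-Grubbs test, blind to
phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, GenomicIntervals, IndividualRecord, VariantRecord, normalize_chrom

__all__ = [
    "SiteClass",
    "QCConfig",
    "ClassificationError",
    "InsufficientDataError",
    "classify_site",
    "qualify_genotype",
    "partition_by_rarity",
    "grubbs_statistic",
    "grubbs_pvalue",
    "grubbs_outliers",
]

AUTOSOMES = {str(i) for i in range(1, 23)}


class ClassificationError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class SiteClass(Enum):
    AUTOSOME = "autosome"
    PAR = "par"
    X_NONPAR = "x_nonpar"
    Y = "y"


@dataclass
class QCConfig:
    """Outlier-exclusion settings: Grubbs significance level and iteration."""

    grubbs_alpha: float = 0.001
    iterate: bool = True

    def __post_init__(self):
        if not 0.0 < self.grubbs_alpha < 1.0:
            raise ValueError("grubbs_alpha must be in (0, 1)")


def classify_site(
    chrom: str, pos: int, par_index: Optional[GenomicIntervals] = None
) -> Optional[SiteClass]:
    """Classify a site as autosome / PAR / X-non-PAR / Y.

    Returns None for mitochondrial and unplaced contigs (excluded from the
    rarity analysis).
    """
    chrom = normalize_chrom(chrom)
    if chrom in AUTOSOMES:
        return SiteClass.AUTOSOME
    if chrom in ("X", "Y"):
        if par_index is not None and par_index.contains(chrom, pos):
            return SiteClass.PAR
        return SiteClass.X_NONPAR if chrom == "X" else SiteClass.Y
    return None


def qualify_genotype(
    site_class: SiteClass, genotype: str, individual: IndividualRecord
) -> bool:
    """Apply the five zygosity rules to one carrier call.

    ``hemi`` is accepted as a synonym of ``hom`` on the sex chromosomes.
    """
    if not isinstance(site_class, SiteClass):
        raise ClassificationError(f"unknown site class {site_class!r}")
    is_homozygous = genotype in ("hom", "hemi")
    xxy = individual.karyotype == "XXY"
    if site_class in (SiteClass.AUTOSOME, SiteClass.PAR):
        return genotype == "het"
    if site_class is SiteClass.X_NONPAR:
        if genotype == "het":
            return individual.sex == "female" or xxy
        if is_homozygous:
            return individual.sex == "male" and not xxy
        return False
    if site_class is SiteClass.Y:
        return is_homozygous and (individual.sex == "male" or xxy)
    raise ClassificationError(f"unknown site class {site_class!r}")


def qualifying_allele_count(
    variant: VariantRecord, cohort: Cohort, par_index: Optional[GenomicIntervals] = None
) -> Optional[int]:
    """Number of carrier alleles passing the zygosity rules (None = off-target contig)."""
    site = classify_site(variant.chrom, variant.pos, par_index)
    if site is None:
        return None
    return sum(
        1
        for ind_id, gt in variant.carriers
        if qualify_genotype(site, gt, cohort.individual(ind_id))
    )


def partition_by_rarity(
    cohort: Cohort,
    excluded_db_flags: Iterable[str] = ("exac", "esp", "tommo"),
    par_index: Optional[GenomicIntervals] = None,
) -> dict:
    """Bin variants into singleton/doubleton/tripleton/common_or_excluded.

    Variants present in any selected external panel are excluded outright;
    the rest are binned by the count of qualifying carrier alleles over the
    full (pre-outlier-removal) cohort. Mitochondrial/unplaced variants are
    excluded with a warning.
    """
    flags = tuple(excluded_db_flags)
    bins: dict = {
        "singleton": [],
        "doubleton": [],
        "tripleton": [],
        "common_or_excluded": [],
    }
    n_offtarget = 0
    for v in cohort.variants:
        if any(v.in_panel(f) for f in flags):
            bins["common_or_excluded"].append(v)
            continue
        count = qualifying_allele_count(v, cohort, par_index)
        if count is None:
            n_offtarget += 1
            bins["common_or_excluded"].append(v)
        elif count == 1:
            bins["singleton"].append(v)
        elif count == 2:
            bins["doubleton"].append(v)
        elif count == 3:
            bins["tripleton"].append(v)
        else:
            bins["common_or_excluded"].append(v)
    if n_offtarget:
        warnings.warn(
            f"excluded {n_offtarget} variant(s) on mitochondrial/unplaced contigs",
            stacklevel=2,
        )
    return bins


def grubbs_statistic(values: np.ndarray) -> tuple:
    """Two-sided Grubbs statistic and the index of the most extreme value."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0, int(np.argmax(np.abs(values - mean)))
    dev = np.abs(values - mean)
    idx = int(np.argmax(dev))
    return float(dev[idx] / sd), idx


def grubbs_pvalue(g: float, n: int) -> float:
    """Two-sided P for the Grubbs statistic via the t-distribution.

    G maps to t through G = ((n-1)/sqrt(n)) * sqrt(t^2/(n-2+t^2)); the
    two-sided P is 2n * P(T_{n-2} >= t), capped at 1.
    """
    if n < 3:
        raise InsufficientDataError("Grubbs test requires at least 3 values")
    if g <= 0:
        return 1.0
    gmax = (n - 1) / np.sqrt(n)
    if g >= gmax:
        return 0.0
    t2 = (g * g * n * (n - 2)) / ((n - 1) ** 2 - g * g * n)
    return float(min(1.0, 2 * n * stats.t.sf(np.sqrt(t2), df=n - 2)))


def grubbs_outliers(values: Sequence[float], config: QCConfig = QCConfig()) -> list:
    """Indices of values excluded by the (iterative) two-sided Grubbs test.

    The most extreme value is removed while its test P falls below
    ``config.grubbs_alpha``; with ``iterate=False`` at most one value is
    removed. Returned indices refer to the original sequence. The decision
    uses only the values themselves (phenotype-blind).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("Grubbs test requires at least 3 values")
    remaining = list(range(values.size))
    excluded: list = []
    while len(remaining) >= 3:
        g, local_idx = grubbs_statistic(values[remaining])
        p = grubbs_pvalue(g, len(remaining))
        if p >= config.grubbs_alpha:
            break
        excluded.append(remaining.pop(local_idx))
        if not config.iterate:
            break
    return excluded
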