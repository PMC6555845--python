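"""Case stratification by pathogenic-variant carrier status.

A case carrying a damaging URV (null or consensus-damaging missense) in
an established disease gene is a *carrier*; the variant is promoted to a
convincingly *pathogenic* URV (pURV) when its inheritance pattern
qualifies:

1. autosomal disease-gene dURV confirmed de novo (including de novo
   calls with mosaicism in one parent),
2. dURV in an X-linked recessive gene (or a gene whose heterozygous
   mutations cause only a mild phenotype) in hemizygous status, either
   maternally transmitted or de novo,
3. heterozygous dURV in a female-specific X-linked gene (PCDH19-type),
   either paternally transmitted or de novo,
4. other X-chromosome disease-gene dURVs confirmed de novo.

Carriers whose dURV fails these rules (inherited from an unaffected
parent, missing parental DNA, mosaic in the proband) remain carriers
without a pURV. Previously-reported-phenotype strata are assigned by an
exact (chrom, pos, ref, alt) join against a user-supplied table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .classify import FunctionalClass
from .cohort import Cohort, GeneSet, VariantRecord, normalize_chrom

__all__ = [
    "ConfigError",
    "PURVStatus",
    "read_trio_calls",
    "read_hgmd_table",
    "assign_purv_status",
    "make_subsets",
]

PURV_RULES = ("autosomal_de_novo", "xlr_hemizygous", "pcdh19_het", "x_de_novo")
HGMD_STRATA = ("non_disease_phenotype", "disease_phenotype", "unknown_or_uncertain",
               "not_registered")
#: Inheritance labels that count as de novo for rule 1/4; the parental-
#: mosaic label is distinguished so it can be reported separately.
DE_NOVO_LABELS = ("de_novo", "de_novo_parental_mosaic")


class ConfigError(ValueError):
    pass


@dataclass
class PURVStatus:
    """Per-case carrier/pathogenic-variant bookkeeping."""

    individual_id: str
    carries_durv_in_known: bool = False
    purv: Optional[VariantRecord] = None
    purv_rule: Optional[str] = None
    purv_class: Optional[FunctionalClass] = None
    parental_mosaic: bool = False
    hgmd_stratum: str = "not_registered"

    def __post_init__(self):
        if self.purv is not None and not self.carries_durv_in_known:
            raise ValueError("a pURV implies carrier status")
        if self.purv_rule is not None and self.purv_rule not in PURV_RULES:
            raise ValueError(f"unknown pURV rule {self.purv_rule!r}")
        if self.hgmd_stratum not in HGMD_STRATA:
            raise ValueError(f"unknown HGMD stratum {self.hgmd_stratum!r}")


def read_trio_calls(path) -> dict:
    """Read trio inheritance calls keyed by (individual, chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["individual", "chrom", "pos", "ref", "alt", "inheritance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"trio call table missing column(s): {', '.join(missing)}")
    return {
        (r.individual, normalize_chrom(r.chrom), int(r.pos), r.ref, r.alt): r.inheritance
        for r in df.itertuples(index=False)
    }


def read_hgmd_table(path) -> dict:
    """Exact-allele phenotype-stratum table keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom", "pos", "ref", "alt", "stratum"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"HGMD stratum table missing column(s): {', '.join(missing)}")
    return {
        (normalize_chrom(r.chrom), int(r.pos), r.ref, r.alt): r.stratum
        for r in df.itertuples(index=False)
    }


def _qualify(
    variant: VariantRecord,
    genotype: str,
    inheritance: Optional[str],
    xlr_genes: frozenset,
    female_specific_genes: frozenset,
) -> Optional[str]:
    """Return the matching pURV rule, or None."""
    on_x = variant.chrom == "X"
    is_de_novo = inheritance in DE_NOVO_LABELS
    if not on_x:
        return "autosomal_de_novo" if is_de_novo else None
    if variant.gene in xlr_genes:
        if genotype in ("hom", "hemi") and (is_de_novo or inheritance == "maternal"):
            return "xlr_hemizygous"
        return None
    if variant.gene in female_specific_genes:
        if genotype == "het" and (is_de_novo or inheritance == "paternal"):
            return "pcdh19_het"
        return None
    return "x_de_novo" if is_de_novo else None


def assign_purv_status(
    cohort: Cohort,
    known_gene_set: GeneSet,
    trio_calls: Mapping[tuple, str],
    xlr_genes: Iterable[str] = None,
    female_specific_genes: Iterable[str] = None,
    hgmd_table: Optional[Mapping[tuple, str]] = None,
) -> dict:
    """Assign carrier and pURV status to every case.

    ``trio_calls`` maps (individual, chrom, pos, ref, alt) to an
    inheritance label (de_novo, de_novo_parental_mosaic, maternal,
    paternal, unknown, mosaic_proband); untested dURVs may be absent.
    Requires classified variants (``functional_class`` set).
    """
    if xlr_genes is None or female_specific_genes is None:
        raise ConfigError(
            "special gene lists (xlr_genes, female_specific_genes) are required; "
            "pass empty collections explicitly if none apply"
        )
    xlr = frozenset(xlr_genes)
    female_specific = frozenset(female_specific_genes)
    durv_leaves = {FunctionalClass.NULL, FunctionalClass.CD_MISSENSE}

    case_ids = set(cohort.case_ids)
    statuses = {cid: PURVStatus(individual_id=cid) for cid in sorted(case_ids)}

    # deterministic variant order: genomic coordinates
    for v in sorted(cohort.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        if v.functional_class not in durv_leaves or v.gene not in known_gene_set:
            continue
        for ind_id, genotype in v.carriers:
            if ind_id not in case_ids:
                continue
            st = statuses[ind_id]
            st.carries_durv_in_known = True
            if st.purv is not None:
                continue  # first qualifying variant wins
            inheritance = trio_calls.get((ind_id, v.chrom, v.pos, v.ref, v.alt))
            rule = _qualify(v, genotype, inheritance, xlr, female_specific)
            if rule is not None:
                st.purv = v
                st.purv_rule = rule
                st.purv_class = v.functional_class
                st.parental_mosaic = inheritance == "de_novo_parental_mosaic"
                if hgmd_table is not None:
                    st.hgmd_stratum = hgmd_table.get(v.key, "not_registered")
    return statuses


def make_subsets(statuses: Mapping[str, PURVStatus]) -> dict:
    """Build the named, nested case subsets used across the analyses."""
    all_cases = set(statuses)
    carriers = {i for i, s in statuses.items() if s.carries_durv_in_known}
    purv = {i for i, s in statuses.items() if s.purv is not None}
    purv_null = {i for i, s in statuses.items()
                 if s.purv_class is FunctionalClass.NULL}
    purv_cd = {i for i, s in statuses.items()
               if s.purv_class is FunctionalClass.CD_MISSENSE}
    by_stratum = {
        f"purv_{stratum}": {
            i for i, s in statuses.items()
            if s.purv is not None and s.hgmd_stratum == stratum
        }
        for stratum in ("non_disease_phenotype", "disease_phenotype",
                        "unknown_or_uncertain")
    }
    # variants never matched against a stratum table fall in the "others" bin
    by_stratum["purv_unknown_or_uncertain"] |= {
        i for i, s in statuses.items()
        if s.purv is not None and s.hgmd_stratum == "not_registered"
    }
    return {
        "all_cases": all_cases,
        "no_known_durv": all_cases - carriers,
        "known_durv_carriers": carriers,
        "purv_carriers": purv,
        "purv_null": purv_null,
        "purv_cd_missense": purv_cd,
        **by_stratum,
    }
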