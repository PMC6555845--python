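"""Functional classification of coding variants.

Leaf taxonomy (mutually exclusive, exhaustive over classified variants):

* ``null`` - loss-of-function: nonsense, frameshift, splice donor/acceptor
  and read-through (stop-lost) calls.
* ``cd_missense`` - consensus-damaging missense: MODERATE-impact variants
  called damaging by all seven predictors (SIFT, PolyPhen-2 HumVar and
  HumDiv, LRT, MutationTaster, MutationAssessor, PROVEAN). A missing
  prediction (NA) in any predictor disqualifies.
* ``other_moderate`` - remaining missense/inframe variants, plus
  protein-protein-contact and start-lost calls reclassified out of the
  HIGH-impact group.
* ``fcdhs_synonymous`` - synonymous within frontal-cortex DNase I
  hypersensitive sites.
* ``sr_synonymous`` - synonymous within the last/first 3 bp of an exon
  adjacent to an intron (splice region).
* ``other_synonymous`` - remaining synonymous.
* ``noncoding`` - MODIFIER-impact (intronic, UTR, intergenic...).

Aggregates: moderate = cd_missense + other_moderate; synonymous = the
three synonymous leaves; durv (damaging URV) = null + cd_missense.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .cohort import Cohort, GenomicIntervals, PREDICTION_ALGORITHMS, VariantRecord

__all__ = [
    "FunctionalClass",
    "ClassifyConfig",
    "ClassificationError",
    "PositionalError",
    "CLASS_GROUPS",
    "resolve_class_group",
    "classify",
    "classify_variants",
    "is_cd_missense",
    "is_sr_synonymous",
]


class ClassificationError(ValueError):
    pass


class PositionalError(ValueError):
    pass


class FunctionalClass(Enum):
    NULL = "null"
    CD_MISSENSE = "cd_missense"
    OTHER_MODERATE = "other_moderate"
    FCDHS_SYNONYMOUS = "fcdhs_synonymous"
    SR_SYNONYMOUS = "sr_synonymous"
    OTHER_SYNONYMOUS = "other_synonymous"
    NONCODING = "noncoding"


#: Aggregate class groups addressable by name in counting and burden tests.
CLASS_GROUPS = {
    "null": frozenset({FunctionalClass.NULL}),
    "cd_missense": frozenset({FunctionalClass.CD_MISSENSE}),
    "other_moderate": frozenset({FunctionalClass.OTHER_MODERATE}),
    "moderate": frozenset({FunctionalClass.CD_MISSENSE, FunctionalClass.OTHER_MODERATE}),
    "fcdhs_synonymous": frozenset({FunctionalClass.FCDHS_SYNONYMOUS}),
    "sr_synonymous": frozenset({FunctionalClass.SR_SYNONYMOUS}),
    "other_synonymous": frozenset({FunctionalClass.OTHER_SYNONYMOUS}),
    "synonymous": frozenset({
        FunctionalClass.FCDHS_SYNONYMOUS,
        FunctionalClass.SR_SYNONYMOUS,
        FunctionalClass.OTHER_SYNONYMOUS,
    }),
    "durv": frozenset({FunctionalClass.NULL, FunctionalClass.CD_MISSENSE}),
    "noncoding": frozenset({FunctionalClass.NONCODING}),
    "coding": frozenset(set(FunctionalClass) - {FunctionalClass.NONCODING}),
}

CODING_CLASSES = CLASS_GROUPS["coding"]


def resolve_class_group(name) -> frozenset:
    """Resolve a class-group name / FunctionalClass / iterable to leaf classes."""
    if isinstance(name, FunctionalClass):
        return frozenset({name})
    if isinstance(name, str):
        try:
            return CLASS_GROUPS[name]
        except KeyError as exc:
            raise ClassificationError(
                f"unknown variant class {name!r}; known: {sorted(CLASS_GROUPS)}"
            ) from exc
    return frozenset().union(*(resolve_class_group(n) for n in name))


# Effect vocabulary (SnpEff-style consequence labels).
NULL_EFFECTS = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_lost",  # read-through
}
#: HIGH-impact consequences reclassified into the Moderate group.
RECLASSIFIED_TO_MODERATE = {"protein_protein_contact", "start_lost"}
MODERATE_EFFECTS = {
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "conservative_inframe_insertion",
    "conservative_inframe_deletion",
    "disruptive_inframe_insertion",
    "disruptive_inframe_deletion",
} | RECLASSIFIED_TO_MODERATE
SYNONYMOUS_EFFECTS = {"synonymous_variant", "stop_retained_variant", "start_retained_variant"}
NONCODING_EFFECTS = {
    "intron_variant",
    "intergenic_region",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
}


@dataclass
class ClassifyConfig:
    """Precedence for synonymous variants that are both splice-region and
    DHS members: splice-region wins by default (``sr_before_dhs=True``)."""

    sr_before_dhs: bool = True


def is_cd_missense(variant: VariantRecord) -> bool:
    """True iff all seven predictors made an affirmative damaging call."""
    flags = variant.damage_flags
    return all(flags.get(a) is True for a in PREDICTION_ALGORITHMS)


def classify(
    variant: VariantRecord,
    dhs_index: Optional[GenomicIntervals] = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> FunctionalClass:
    """Assign a variant to its leaf functional class."""
    effect, impact = variant.effect, variant.impact.upper()

    if effect in RECLASSIFIED_TO_MODERATE:
        return (
            FunctionalClass.CD_MISSENSE
            if is_cd_missense(variant)
            else FunctionalClass.OTHER_MODERATE
        )
    if effect in NULL_EFFECTS or (impact == "HIGH" and effect not in RECLASSIFIED_TO_MODERATE):
        if effect in NULL_EFFECTS:
            return FunctionalClass.NULL
        raise ClassificationError(f"unknown HIGH-impact effect label {effect!r}")
    if effect in MODERATE_EFFECTS or impact == "MODERATE":
        if effect not in MODERATE_EFFECTS:
            raise ClassificationError(f"unknown MODERATE-impact effect label {effect!r}")
        return (
            FunctionalClass.CD_MISSENSE
            if is_cd_missense(variant)
            else FunctionalClass.OTHER_MODERATE
        )
    if effect in SYNONYMOUS_EFFECTS:
        in_sr = variant.splice_region
        in_dhs = dhs_index is not None and dhs_index.contains(variant.chrom, variant.pos)
        if config.sr_before_dhs:
            if in_sr:
                return FunctionalClass.SR_SYNONYMOUS
            if in_dhs:
                return FunctionalClass.FCDHS_SYNONYMOUS
        else:
            if in_dhs:
                return FunctionalClass.FCDHS_SYNONYMOUS
            if in_sr:
                return FunctionalClass.SR_SYNONYMOUS
        return FunctionalClass.OTHER_SYNONYMOUS
    if effect in NONCODING_EFFECTS or impact == "MODIFIER":
        return FunctionalClass.NONCODING
    raise ClassificationError(f"unknown effect label {effect!r} (impact {impact})")


def classify_variants(
    cohort: Cohort,
    dhs_index: Optional[GenomicIntervals] = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> None:
    """Classify every variant in place (sets ``variant.functional_class``)."""
    for v in cohort.variants:
        v.functional_class = classify(v, dhs_index, config)


def is_sr_synonymous(variant: VariantRecord, exons: Sequence[tuple]) -> bool:
    """Splice-region test against an exon model.

    ``exons`` is the transcript's exon list as 1-based closed intervals in
    transcript order along the genome. A position qualifies when it lies
    within the first or last 3 bp of an exon boundary that abuts an intron
    (so the outermost transcript ends never qualify).
    """
    exons = sorted((int(s), int(e)) for s, e in exons)
    pos = variant.pos
    for i, (start, end) in enumerate(exons):
        if not start <= pos <= end:
            continue
        has_intron_before = i > 0
        has_intron_after = i < len(exons) - 1
        if has_intron_before and pos - start < 3:
            return True
        if has_intron_after and end - pos < 3:
            return True
        return False
    raise PositionalError(
        f"position {variant.chrom}:{pos} falls outside every exon of the model"
    )
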