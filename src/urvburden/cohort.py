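"""Core cohort data model and flat-file readers/writers.

The statistical pipeline operates on three tables: an annotated variant
table (one row per alt allele, flattened from an annotated VCF), a sample
manifest with case/control status and regression covariates, and a
per-gene metadata table (pLI, per-consequence de novo mutation rates).
Genomic intervals (DNase hypersensitive sites, pseudoautosomal regions)
come in as BED.

Coordinate conventions: variant positions are 1-based (VCF convention);
intervals are 0-based half-open (BED convention). The conversion happens
exactly once, inside :class:`GenomicIntervals.contains`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SchemaError",
    "IntegrityError",
    "PREDICTION_ALGORITHMS",
    "EXTERNAL_PANELS",
    "VariantRecord",
    "IndividualRecord",
    "GeneInfo",
    "GeneSet",
    "Cohort",
    "GenomicIntervals",
    "normalize_chrom",
    "read_cohort",
    "write_cohort",
    "read_intervals",
    "read_gene_set",
]


class SchemaError(ValueError):
    """A table does not conform to the expected column schema."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


#: The seven in-silico missense deleteriousness predictors whose unanimous
#: "damaging" call defines the consensus-damaging (CD) missense class.
PREDICTION_ALGORITHMS = (
    "sift",
    "pph2_var",
    "pph2_div",
    "lrt",
    "mutation_taster",
    "mutation_assessor",
    "provean",
)

#: External population panels used to pre-filter rare variants. ``extra``
#: is a generic slot for an additional user-supplied exclusion list (for
#: example a gnomAD-derived one).
EXTERNAL_PANELS = ("exac", "esp", "tommo", "extra")

GENOTYPES = ("het", "hom", "hemi")

MU_CONSEQUENCES = ("nonsense", "frameshift", "splice_site", "missense", "synonymous")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name by stripping any ``chr`` prefix."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if chrom == "M":
        chrom = "MT"
    return chrom


@dataclass
class VariantRecord:
    """One cohort variant (single alt allele) with its annotations.

    ``damage_flags`` maps each of the seven predictors to True (damaging),
    False (tolerated) or None (no prediction). ``carriers`` lists
    ``(individual_id, genotype)`` pairs, genotype in {het, hom, hemi}.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    impact: str
    damage_flags: dict = field(default_factory=dict)
    splice_region: bool = False
    carriers: list = field(default_factory=list)
    external_db: dict = field(default_factory=dict)
    cohort_allele_count: int = 1
    functional_class: Optional[object] = None  # set by functional classification

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty strings")
        if "," in self.alt:
            raise SchemaError(
                f"multi-allelic record at {self.chrom}:{self.pos} (alt={self.alt!r}); "
                "split to one row per alt allele before loading"
            )
        if not self.carriers:
            raise ValueError(f"variant {self.key} has no carriers")
        for _, gt in self.carriers:
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r} at {self.key}")
        if self.cohort_allele_count < 1:
            raise ValueError("cohort_allele_count must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def in_panel(self, panel: str) -> bool:
        return bool(self.external_db.get(panel, False))


@dataclass
class IndividualRecord:
    """A cohort member with status, sex/karyotype and regression covariates."""

    id: str
    status: str  # "case" | "control"
    sex: str  # "male" | "female"
    karyotype: str = "normal"  # "normal" | "XXY"
    callable_fraction: float = 1.0
    pcs: tuple = field(default_factory=lambda: (0.0,) * 10)
    class_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.karyotype not in ("normal", "XXY"):
            raise ValueError(f"karyotype must be normal/XXY, got {self.karyotype!r}")
        if not 0.0 <= self.callable_fraction <= 1.0:
            raise ValueError("callable_fraction must be in [0, 1]")
        self.pcs = tuple(float(x) for x in self.pcs)
        if len(self.pcs) != 10:
            raise ValueError(f"exactly 10 principal components required, got {len(self.pcs)}")
        for k, v in self.class_counts.items():
            if v < 0:
                raise ValueError(f"negative class count for {k}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(frozen=True)
class GeneInfo:
    """Per-gene pLI and per-haploid de novo mutation rates by consequence."""

    gene: str
    pli: float
    mu: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI must be in [0, 1], got {self.pli}")
        for k, v in self.mu.items():
            if v < 0:
                raise ValueError(f"negative mutation rate {k}={v} for {self.gene}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Cohort:
    """Validated container tying variants, individuals and gene metadata."""

    individuals: list
    variants: list
    genes: dict = field(default_factory=dict)
    unannotated_genes: set = field(default_factory=set)

    def __post_init__(self):
        ids = {ind.id for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise IntegrityError("duplicate individual ids in manifest")
        for v in self.variants:
            for carrier_id, _ in v.carriers:
                if carrier_id not in ids:
                    raise IntegrityError(
                        f"variant {v.key} carried by unknown individual {carrier_id!r}"
                    )
        if self.genes:
            self.unannotated_genes |= {
                v.gene for v in self.variants if v.gene not in self.genes
            }

    @property
    def individual_ids(self) -> list:
        return [ind.id for ind in self.individuals]

    @property
    def case_ids(self) -> list:
        return [ind.id for ind in self.individuals if ind.is_case]

    @property
    def control_ids(self) -> list:
        return [ind.id for ind in self.individuals if not ind.is_case]

    def individual(self, ind_id: str) -> IndividualRecord:
        if not hasattr(self, "_index") or len(self._index) != len(self.individuals):
            self._index = {ind.id: ind for ind in self.individuals}
        return self._index[ind_id]


class GenomicIntervals:
    """Point-queryable index over 0-based half-open genomic intervals."""

    def __init__(self, intervals: Iterable[tuple] = ()):
        self._trees: dict = {}
        self.n = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        start, end = int(start), int(end)
        if start >= end:
            raise SchemaError(f"interval start >= end: {chrom}:{start}-{end}")
        self._trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(start, end)
        self.n += 1

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based position (converted internally to 0-based)."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return False
        return bool(tree[int(pos_1based) - 1])

    def __len__(self) -> int:
        return self.n


# ---------------------------------------------------------------------------
# Readers / writers

VARIANT_COLUMNS = (
    ["chrom", "pos", "ref", "alt", "gene", "effect", "impact"]
    + list(PREDICTION_ALGORITHMS)
    + ["splice_region", "in_exac", "in_esp", "in_tommo", "carriers"]
)
MANIFEST_COLUMNS = ["id", "status", "sex", "karyotype", "callable_fraction"] + [
    f"pc{i}" for i in range(1, 11)
]
GENE_COLUMNS = ["gene", "pli"] + [f"mu_{c}" for c in
                                  ("nonsense", "frameshift", "splice", "missense", "synonymous")]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing mandatory column(s): {', '.join(missing)}")


def _parse_flag(value) -> Optional[bool]:
    s = str(value).strip().upper()
    if s == "D":
        return True
    if s == "T":
        return False
    if s in ("NA", "NAN", ".", ""):
        return None
    raise SchemaError(f"prediction value must be D/T/NA, got {value!r}")


def _parse_carriers(cell: str) -> list:
    carriers = []
    for item in str(cell).split(","):
        item = item.strip()
        if not item:
            continue
        try:
            ind_id, gt = item.split(":")
        except ValueError as exc:
            raise SchemaError(f"malformed carrier entry {item!r}") from exc
        carriers.append((ind_id, gt))
    return carriers


def read_cohort(variant_table_path, sample_manifest_path, gene_info_path=None) -> Cohort:
    """Load and validate a cohort from the flat-file schemas.

    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` when a carrier id is absent from the manifest.
    """
    vdf = pd.read_csv(variant_table_path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(vdf, VARIANT_COLUMNS, "variant table")
    mdf = pd.read_csv(sample_manifest_path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(mdf, MANIFEST_COLUMNS, "sample manifest")

    individuals = []
    for row in mdf.itertuples(index=False):
        individuals.append(
            IndividualRecord(
                id=row.id,
                status=row.status,
                sex=row.sex,
                karyotype=row.karyotype,
                callable_fraction=float(row.callable_fraction),
                pcs=tuple(float(getattr(row, f"pc{i}")) for i in range(1, 11)),
            )
        )

    variants = []
    for row in vdf.itertuples(index=False):
        carriers = _parse_carriers(row.carriers)
        external = {
            "exac": row.in_exac == "1",
            "esp": row.in_esp == "1",
            "tommo": row.in_tommo == "1",
        }
        if "in_extra" in vdf.columns:
            external["extra"] = getattr(row, "in_extra") == "1"
        variants.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                effect=row.effect,
                impact=row.impact,
                damage_flags={a: _parse_flag(getattr(row, a)) for a in PREDICTION_ALGORITHMS},
                splice_region=row.splice_region == "1",
                carriers=carriers,
                external_db=external,
                cohort_allele_count=len(carriers),
            )
        )

    genes: dict = {}
    if gene_info_path is not None:
        gdf = pd.read_csv(gene_info_path, sep="\t", float_precision="round_trip")
        _require_columns(gdf, GENE_COLUMNS, "gene info table")
        for row in gdf.itertuples(index=False):
            genes[row.gene] = GeneInfo(
                gene=row.gene,
                pli=float(row.pli),
                mu={
                    "nonsense": float(row.mu_nonsense),
                    "frameshift": float(row.mu_frameshift),
                    "splice_site": float(row.mu_splice),
                    "missense": float(row.mu_missense),
                    "synonymous": float(row.mu_synonymous),
                },
            )

    return Cohort(individuals=individuals, variants=variants, genes=genes)


def _flag_repr(value: Optional[bool]) -> str:
    return "NA" if value is None else ("D" if value else "T")


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort back to the flat-file schemas; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "variants": os.path.join(out_dir, "variants.tsv"),
        "manifest": os.path.join(out_dir, "samples.tsv"),
        "genes": os.path.join(out_dir, "genes.tsv"),
    }
    vrows = []
    has_extra = any("extra" in v.external_db for v in cohort.variants)
    for v in cohort.variants:
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "effect": v.effect, "impact": v.impact,
        }
        for a in PREDICTION_ALGORITHMS:
            row[a] = _flag_repr(v.damage_flags.get(a))
        row["splice_region"] = int(v.splice_region)
        row["in_exac"] = int(v.in_panel("exac"))
        row["in_esp"] = int(v.in_panel("esp"))
        row["in_tommo"] = int(v.in_panel("tommo"))
        if has_extra:
            row["in_extra"] = int(v.in_panel("extra"))
        row["carriers"] = ",".join(f"{i}:{g}" for i, g in v.carriers)
        vrows.append(row)
    pd.DataFrame(vrows).to_csv(paths["variants"], sep="\t", index=False)

    mrows = []
    for ind in cohort.individuals:
        row = {
            "id": ind.id, "status": ind.status, "sex": ind.sex,
            "karyotype": ind.karyotype,
            "callable_fraction": repr(float(ind.callable_fraction)),
        }
        for i, pc in enumerate(ind.pcs, start=1):
            row[f"pc{i}"] = repr(float(pc))
        mrows.append(row)
    pd.DataFrame(mrows).to_csv(paths["manifest"], sep="\t", index=False)

    grows = []
    for g in cohort.genes.values():
        grows.append({
            "gene": g.gene, "pli": repr(float(g.pli)),
            "mu_nonsense": repr(float(g.mu.get("nonsense", 0.0))),
            "mu_frameshift": repr(float(g.mu.get("frameshift", 0.0))),
            "mu_splice": repr(float(g.mu.get("splice_site", 0.0))),
            "mu_missense": repr(float(g.mu.get("missense", 0.0))),
            "mu_synonymous": repr(float(g.mu.get("synonymous", 0.0))),
        })
    pd.DataFrame(grows).to_csv(paths["genes"], sep="\t", index=False)
    return paths


def read_intervals(bed_path) -> GenomicIntervals:
    """Read a BED file (0-based half-open) into a point-queryable index."""
    index = GenomicIntervals()
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise SchemaError(f"malformed BED line: {line!r}")
            index.add(parts[0], int(parts[1]), int(parts[2]))
    return index


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Read a gene set from a one-gene-per-line file."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(genes) != len(set(genes)):
        raise SchemaError(f"duplicate gene ids in gene set file {path}")
    return GeneSet(name=name or os.path.basename(str(path)), genes=frozenset(genes))
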