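"""Synthetic cohorts, trio DNM counts and expression matrices.

The generator emulates the statistical structure the analysis assumes:

* ~743 cases / ~2366 controls whose per-individual coding ultra-rare
  variant totals are approximately normal (mean 54.4, SD 8.2), split
  multinomially across the functional leaf classes with proportions
  taken from the study-scale class totals (null 12,032; consensus-
  damaging missense 12,337; other moderate 96,726; DHS synonymous
  11,247; splice-region synonymous 1,277; other synonymous 35,395 of
  169,014 coding variants), plus Poisson noncoding counts;
* case status drawn from a prospective logistic liability on the
  damaging-variant counts (small odds ratios outside the known disease
  gene set, large ones inside it) plus weak covariate effects, with the
  intercept solved so the expected case fraction matches the design;
* variants materialized as singleton records whose annotations
  (consequence label, impact, the seven predictor flags, splice-region
  flag, DHS position) reproduce the intended class under the functional
  classifier, with configurable doubleton/tripleton and external-panel
  fractions exercising the rarity partition.

Every draw flows from one integer seed; the returned ground truth
records the planted parameters for recovery tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import FunctionalClass
from .cohort import (
    Cohort,
    GeneInfo,
    GeneSet,
    GenomicIntervals,
    IndividualRecord,
    VariantRecord,
    write_cohort,
)
from .dnm import RateScaling, damaging_rate

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_TISSUES",
    "BRAIN_TISSUES",
    "simulate_cohort",
    "simulate_trio_dnms",
    "simulate_expression",
    "write_simulated",
]

# Exclusive coding leaf-class proportions from the study-scale totals.
DEFAULT_CLASS_PROPORTIONS = {
    FunctionalClass.NULL: 12_032 / 169_014,
    FunctionalClass.CD_MISSENSE: 12_337 / 169_014,
    FunctionalClass.OTHER_MODERATE: 96_726 / 169_014,
    FunctionalClass.FCDHS_SYNONYMOUS: 11_247 / 169_014,
    FunctionalClass.SR_SYNONYMOUS: 1_277 / 169_014,
    FunctionalClass.OTHER_SYNONYMOUS: 35_395 / 169_014,
}

# Per-URV odds ratios planted on damaging classes, by gene-set membership.
DEFAULT_CLASS_OR = {
    ("null", "known"): 4.0,
    ("cd_missense", "known"): 3.0,
    ("null", "other"): 1.09,
    ("cd_missense", "other"): 1.06,
}

NULL_EFFECT_CHOICES = (
    "stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant",
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 743
    n_controls: int = 2366
    mean_urv_count: float = 54.4
    sd_urv_count: float = 8.2
    noncoding_mean: float = 42_974 / 3_109
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    class_or: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_OR))
    n_genes: int = 2000
    known_set_size: int = 58
    doubleton_fraction: float = 45_832 / 169_014
    tripleton_fraction: float = 20_786 / 169_014
    db_present_fraction: float = 0.10
    callable_mean: float = 0.967
    callable_sd: float = 0.0074
    sex_beta: float = 0.1
    pc1_beta: float = 0.05
    mu_scale: float = 1.0
    materialize_variants: bool = True  # False: counts-only cohort (fast calibration runs)
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        for key, or_ in self.class_or.items():
            if or_ <= 0:
                raise ValueError(f"odds ratio for {key} must be > 0")
        if self.known_set_size >= self.n_genes:
            raise ValueError("known_set_size must be smaller than n_genes")


@dataclass
class GroundTruth:
    """Planted parameters and bookkeeping emitted alongside the cohort."""

    config: SimConfig
    intercept: float
    known_genes: GeneSet
    gene_table: pd.DataFrame  # gene, chrom, start, end, weight, pli
    dhs_index: GenomicIntervals
    counts: pd.DataFrame  # per-individual per-(leaf, partition) singleton counts
    liability: pd.Series  # per-individual case probability
    n_singletons: int = 0
    n_doubletons: int = 0
    n_tripletons: int = 0
    n_db_flagged: int = 0

    def class_counts(self, class_group) -> pd.Series:
        """Per-individual singleton count over a leaf class or group name."""
        from .classify import resolve_class_group

        leaves = resolve_class_group(class_group)
        cols = [c for c in self.counts.columns
                if FunctionalClass(c.split("|")[0]) in leaves]
        return self.counts[cols].sum(axis=1)


def _solve_intercept(offsets: np.ndarray, target: float) -> float:
    lo, hi = -30.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + offsets)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _make_genes(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_genes
    ids = np.array([f"G{i:05d}" for i in range(n)])
    lengths = np.clip(rng.lognormal(mean=8.0, sigma=0.6, size=n), 500, 100_000).astype(int)
    weight = lengths / lengths.sum()
    # bimodal pLI: mostly LOF-tolerant genes with a constrained minority
    tolerant = rng.beta(0.5, 8.0, size=n)
    constrained = rng.beta(8.0, 0.5, size=n)
    pli = np.where(rng.random(n) < 0.25, constrained, tolerant)

    chroms = np.array([str(1 + (i % 22)) for i in range(n)])
    starts = np.empty(n, dtype=np.int64)
    cursor: dict = {}
    for i in range(n):
        c = chroms[i]
        starts[i] = cursor.get(c, 10_000)
        cursor[c] = starts[i] + lengths[i] + 5_000
    ends = starts + lengths

    # DHS window: first fifth of every gene body
    dhs = GenomicIntervals()
    dhs_ends = starts + np.maximum(lengths // 5, 10)
    for c, s, e in zip(chroms, starts, dhs_ends):
        dhs.add(c, int(s), int(e))

    base = cfg.mu_scale * lengths / lengths.mean()
    gene_infos = {}
    for i, g in enumerate(ids):
        gene_infos[g] = GeneInfo(
            gene=g,
            pli=float(pli[i]),
            mu={
                "nonsense": 0.9e-6 * base[i],
                "frameshift": 0.7e-6 * base[i],
                "splice_site": 0.45e-6 * base[i],
                "missense": 1.1e-5 * base[i],
                "synonymous": 0.5e-5 * base[i],
            },
        )
    known = ids[np.argsort(pli)[::-1][: cfg.known_set_size]]
    table = pd.DataFrame({
        "gene": ids, "chrom": chroms, "start": starts, "end": ends,
        "dhs_end": dhs_ends, "weight": weight, "pli": pli,
    }).set_index("gene", drop=False)
    return gene_infos, table, dhs, GeneSet(name="known_disease_genes", genes=frozenset(known))


def _variant_annotations(leaf: FunctionalClass, rng: np.random.Generator):
    """(effect, impact, damage_flags, splice_region) reproducing ``leaf``."""
    from .cohort import PREDICTION_ALGORITHMS

    flags = dict.fromkeys(PREDICTION_ALGORITHMS, None)
    if leaf is FunctionalClass.NULL:
        return rng.choice(NULL_EFFECT_CHOICES), "HIGH", flags, False
    if leaf is FunctionalClass.CD_MISSENSE:
        return "missense_variant", "MODERATE", dict.fromkeys(PREDICTION_ALGORITHMS, True), False
    if leaf is FunctionalClass.OTHER_MODERATE:
        flags = dict.fromkeys(PREDICTION_ALGORITHMS, True)
        spoiled = rng.choice(PREDICTION_ALGORITHMS)
        flags[spoiled] = False if rng.random() < 0.5 else None
        if rng.random() < 0.1:
            return "inframe_deletion", "MODERATE", dict.fromkeys(PREDICTION_ALGORITHMS, None), False
        return "missense_variant", "MODERATE", flags, False
    if leaf is FunctionalClass.SR_SYNONYMOUS:
        return "synonymous_variant", "LOW", flags, True
    if leaf in (FunctionalClass.FCDHS_SYNONYMOUS, FunctionalClass.OTHER_SYNONYMOUS):
        return "synonymous_variant", "LOW", flags, False
    return "intron_variant", "MODIFIER", flags, False


_BASES = np.array(list("ACGT"))


def _positions_for(leaf, gene_rows, rng):
    """Vectorized positions: DHS leaf inside the window, others outside."""
    starts = gene_rows["start"].to_numpy()
    dhs_ends = gene_rows["dhs_end"].to_numpy()
    ends = gene_rows["end"].to_numpy()
    if leaf is FunctionalClass.FCDHS_SYNONYMOUS:
        lo, hi = starts, dhs_ends
    else:
        lo, hi = dhs_ends, ends
    return (lo + rng.random(len(starts)) * (hi - lo)).astype(np.int64) + 1


def simulate_cohort(config: SimConfig = SimConfig()):
    """Generate a cohort and its ground truth. Deterministic per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_infos, gene_table, dhs, known = _make_genes(cfg, rng)
    n = cfg.n_cases + cfg.n_controls
    ids = np.array([f"S{i:05d}" for i in range(n)])

    # covariates
    sex_male = rng.random(n) < 0.5
    karyotype = np.where((rng.random(n) < 0.002) & sex_male, "XXY", "normal")
    var = cfg.callable_sd**2
    m = cfg.callable_mean
    common = m * (1 - m) / var - 1.0
    callable_frac = rng.beta(m * common, (1 - m) * common, size=n)
    pcs = rng.standard_normal((n, 10))

    # per-individual coding totals and leaf splits
    totals = np.clip(np.rint(rng.normal(cfg.mean_urv_count, cfg.sd_urv_count, size=n)),
                     0, None).astype(int)
    leaves = list(cfg.class_proportions)
    props = np.array([cfg.class_proportions[c] for c in leaves])
    leaf_counts = rng.multinomial(totals, props / props.sum())
    noncoding_counts = rng.poisson(cfg.noncoding_mean, size=n)

    # known / other partition of each damaging leaf count
    known_mask = gene_table["gene"].isin(known.genes).to_numpy()
    w = gene_table["weight"].to_numpy()
    p_known = float(w[known_mask].sum())
    counts: dict = {}
    for j, leaf in enumerate(leaves):
        counts[(leaf, "known")] = rng.binomial(leaf_counts[:, j], p_known)
        counts[(leaf, "other")] = leaf_counts[:, j] - counts[(leaf, "known")]
    counts[(FunctionalClass.NONCODING, "other")] = noncoding_counts
    counts[(FunctionalClass.NONCODING, "known")] = np.zeros(n, dtype=int)

    # liability and status
    log_or = np.zeros(n)
    for (class_name, part), or_ in cfg.class_or.items():
        leaf = FunctionalClass(class_name)
        log_or = log_or + np.log(or_) * counts[(leaf, part)]
    offsets = log_or + cfg.sex_beta * sex_male + cfg.pc1_beta * pcs[:, 0]
    target = cfg.n_cases / n
    intercept = _solve_intercept(offsets, target)
    prob = 1.0 / (1.0 + np.exp(-(intercept + offsets)))
    is_case = rng.random(n) < prob

    individuals = []
    for i in range(n):
        class_counts = {leaf.value: int(leaf_counts[i, j]) for j, leaf in enumerate(leaves)}
        class_counts["noncoding"] = int(noncoding_counts[i])
        individuals.append(IndividualRecord(
            id=str(ids[i]),
            status="case" if is_case[i] else "control",
            sex="male" if sex_male[i] else "female",
            karyotype=str(karyotype[i]),
            callable_fraction=float(callable_frac[i]),
            pcs=tuple(pcs[i]),
            class_counts=class_counts,
        ))

    # materialize singleton variants
    variants: list = []
    w_known = w * known_mask
    w_other = w * ~known_mask
    partitions = {"known": w_known / w_known.sum(), "other": w_other / w_other.sum()}
    gene_idx = np.arange(cfg.n_genes)
    from .cohort import PREDICTION_ALGORITHMS

    clean_db = {"exac": False, "esp": False, "tommo": False}
    for (leaf, part), per_ind in counts.items():
        total_k = int(per_ind.sum())
        if total_k == 0 or not cfg.materialize_variants:
            continue
        carrier_ids = np.repeat(ids, per_ind)
        gidx = rng.choice(gene_idx, size=total_k, p=partitions[part])
        rows = gene_table.iloc[gidx]
        chrom_arr = rows["chrom"].to_numpy()
        gene_arr = rows["gene"].to_numpy()
        positions = _positions_for(leaf, rows, rng)
        ref_idx = rng.integers(0, 4, size=total_k)
        alt_idx = (ref_idx + rng.integers(1, 4, size=total_k)) % 4
        refs, alts = _BASES[ref_idx], _BASES[alt_idx]

        impact, splice_region = {
            FunctionalClass.NULL: ("HIGH", False),
            FunctionalClass.CD_MISSENSE: ("MODERATE", False),
            FunctionalClass.OTHER_MODERATE: ("MODERATE", False),
            FunctionalClass.FCDHS_SYNONYMOUS: ("LOW", False),
            FunctionalClass.SR_SYNONYMOUS: ("LOW", True),
            FunctionalClass.OTHER_SYNONYMOUS: ("LOW", False),
            FunctionalClass.NONCODING: ("MODIFIER", False),
        }[leaf]
        if leaf is FunctionalClass.NULL:
            effects = rng.choice(NULL_EFFECT_CHOICES, size=total_k)
        elif leaf in (FunctionalClass.CD_MISSENSE, FunctionalClass.OTHER_MODERATE):
            effects = np.full(total_k, "missense_variant", dtype=object)
        elif leaf is FunctionalClass.NONCODING:
            effects = np.full(total_k, "intron_variant", dtype=object)
        else:
            effects = np.full(total_k, "synonymous_variant", dtype=object)
        if leaf is FunctionalClass.OTHER_MODERATE:
            inframe = rng.random(total_k) < 0.1
            effects[inframe] = "inframe_deletion"
            spoiled = rng.integers(0, len(PREDICTION_ALGORITHMS), size=total_k)
            spoil_na = rng.random(total_k) < 0.5

        for k in range(total_k):
            if leaf is FunctionalClass.CD_MISSENSE:
                flags = dict.fromkeys(PREDICTION_ALGORITHMS, True)
            elif leaf is FunctionalClass.OTHER_MODERATE:
                if effects[k] == "inframe_deletion":
                    flags = dict.fromkeys(PREDICTION_ALGORITHMS, None)
                else:
                    flags = dict.fromkeys(PREDICTION_ALGORITHMS, True)
                    flags[PREDICTION_ALGORITHMS[spoiled[k]]] = None if spoil_na[k] else False
            else:
                flags = dict.fromkeys(PREDICTION_ALGORITHMS, None)
            variants.append(VariantRecord(
                chrom=str(chrom_arr[k]),
                pos=int(positions[k]),
                ref=str(refs[k]), alt=str(alts[k]),
                gene=str(gene_arr[k]),
                effect=str(effects[k]), impact=impact,
                damage_flags=flags, splice_region=splice_region,
                carriers=[(str(carrier_ids[k]), "het")],
                external_db=dict(clean_db),
            ))
    n_singletons = len(variants)

    # extra variants exercising the rarity partition
    def _extra(n_extra: int, n_carriers: int, db_flag: bool) -> int:
        made = 0
        if n_extra <= 0:
            return 0
        leaf_draw = rng.choice(len(leaves), size=n_extra, p=props / props.sum())
        gidx = rng.choice(gene_idx, size=n_extra, p=w)
        chrom_arr = gene_table["chrom"].to_numpy()[gidx]
        gene_arr = gene_table["gene"].to_numpy()[gidx]
        lo = gene_table["dhs_end"].to_numpy()[gidx]
        hi = np.maximum(gene_table["end"].to_numpy()[gidx], lo + 1)
        positions = (lo + rng.random(n_extra) * (hi - lo)).astype(np.int64) + 1
        ref_idx = rng.integers(0, 4, size=n_extra)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_extra)) % 4
        for k in range(n_extra):
            leaf = leaves[int(leaf_draw[k])]
            effect, impact, flags, sr = _variant_annotations(leaf, rng)
            carriers = [(str(cid), "het")
                        for cid in rng.choice(ids, size=n_carriers, replace=False)]
            variants.append(VariantRecord(
                chrom=str(chrom_arr[k]), pos=int(positions[k]),
                ref=str(_BASES[ref_idx[k]]), alt=str(_BASES[alt_idx[k]]),
                gene=str(gene_arr[k]), effect=str(effect), impact=impact,
                damage_flags=flags, splice_region=sr, carriers=carriers,
                external_db={"exac": db_flag, "esp": False, "tommo": False},
                cohort_allele_count=n_carriers,
            ))
            made += 1
        return made

    if cfg.materialize_variants:
        n_doub = _extra(int(round(cfg.doubleton_fraction * n_singletons)), 2, False)
        n_trip = _extra(int(round(cfg.tripleton_fraction * n_singletons)), 3, False)
        n_db = _extra(int(round(cfg.db_present_fraction * n_singletons)), 1, True)
    else:
        n_doub = n_trip = n_db = 0

    cohort = Cohort(individuals=individuals, variants=variants, genes=gene_infos)
    count_df = pd.DataFrame(
        {f"{leaf.value}|{part}": per_ind for (leaf, part), per_ind in counts.items()},
        index=[str(i) for i in ids],
    )
    truth = GroundTruth(
        config=cfg,
        intercept=intercept,
        known_genes=known,
        gene_table=gene_table,
        dhs_index=dhs,
        counts=count_df,
        liability=pd.Series(prob, index=[str(i) for i in ids]),
        n_singletons=n_singletons,
        n_doubletons=n_doub,
        n_tripletons=n_trip,
        n_db_flagged=n_db,
    )
    return cohort, truth


def simulate_trio_dnms(
    gene_infos: Mapping[str, GeneInfo],
    n_trios: int,
    enriched_genes: Iterable[str] = (),
    fold: float = 1.0,
    seed: int = 0,
    scaling: RateScaling = RateScaling(),
) -> pd.Series:
    """Per-gene damaging DNM counts, Poisson under the rate model.

    Counts ~ Poisson((mu_null + mu_cd) * 2 * n_trios * fold_g) with
    fold_g = ``fold`` for enriched genes and 1 otherwise.
    """
    rng = np.random.default_rng(seed)
    enriched = frozenset(enriched_genes)
    genes = sorted(gene_infos)
    lam = np.empty(len(genes))
    for i, g in enumerate(genes):
        mu_null, mu_cd = damaging_rate(gene_infos[g], scaling)
        lam[i] = (mu_null + mu_cd) * 2 * n_trios * (fold if g in enriched else 1.0)
    return pd.Series(rng.poisson(lam), index=genes, name="dnm_count")


DEFAULT_TISSUES = tuple(
    [f"Brain - Region {i:02d}" for i in range(1, 14)]
    + [f"Tissue {i:02d}" for i in range(1, 41)]
)
BRAIN_TISSUES = tuple(t for t in DEFAULT_TISSUES if t.startswith("Brain"))


def simulate_expression(
    genes: Sequence[str],
    tissues: Sequence[str] = DEFAULT_TISSUES,
    brain_labels: Sequence[str] = BRAIN_TISSUES,
    brain_bias: float = 4.0,
    elevated_genes: Iterable[str] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal TPM matrix (genes x tissues).

    ``elevated_genes`` get their expression multiplied by ``brain_bias``
    in the brain tissues, so they preferentially enter brain TPM>10 sets.
    """
    if not len(tissues):
        raise ValueError("tissues must be non-empty")
    rng = np.random.default_rng(seed)
    tpm = rng.lognormal(mean=1.5, sigma=1.5, size=(len(genes), len(tissues)))
    df = pd.DataFrame(tpm, index=list(genes), columns=list(tissues))
    elevated = [g for g in elevated_genes if g in df.index]
    brain = [t for t in brain_labels if t in df.columns]
    if elevated and brain:
        df.loc[elevated, brain] *= brain_bias
    return df


def write_simulated(cohort: Cohort, truth: GroundTruth, out_dir) -> dict:
    """Write the cohort tables plus gene set, DHS BED and ground-truth JSON."""
    paths = write_cohort(cohort, out_dir)
    paths["known_genes"] = os.path.join(out_dir, "known_genes.txt")
    with open(paths["known_genes"], "w") as fh:
        fh.write("\n".join(sorted(truth.known_genes.genes)) + "\n")
    paths["dhs"] = os.path.join(out_dir, "dhs.bed")
    with open(paths["dhs"], "w") as fh:
        for row in truth.gene_table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.dhs_end}\n")
    paths["ground_truth"] = os.path.join(out_dir, "ground_truth.json")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.config.seed,
                "intercept": truth.intercept,
                "class_or": {f"{c}|{p}": v for (c, p), v in truth.config.class_or.items()},
                "known_genes": sorted(truth.known_genes.genes),
                "n_singletons": truth.n_singletons,
                "n_doubletons": truth.n_doubletons,
                "n_tripletons": truth.n_tripletons,
                "n_db_flagged": truth.n_db_flagged,
            },
            fh, indent=2,
        )
    return paths
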