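"""Shared fixtures: hand-written tiny tables and a moderate synthetic cohort."""

import pytest

from urvburden import classify_variants
from urvburden.cohort import VariantRecord, IndividualRecord
from urvburden.simulate import SimConfig, simulate_cohort


def make_individual(ind_id="S1", status="control", sex="female", karyotype="normal",
                    callable_fraction=0.97, pcs=None):
    return IndividualRecord(
        id=ind_id, status=status, sex=sex, karyotype=karyotype,
        callable_fraction=callable_fraction, pcs=pcs or (0.0,) * 10,
    )


def make_variant(chrom="1", pos=100, ref="A", alt="T", gene="G1",
                 effect="missense_variant", impact="MODERATE", flags=None,
                 splice_region=False, carriers=None, external_db=None):
    from urvburden.cohort import PREDICTION_ALGORITHMS

    if flags is None:
        flags = dict.fromkeys(PREDICTION_ALGORITHMS, None)
    elif isinstance(flags, bool):
        flags = dict.fromkeys(PREDICTION_ALGORITHMS, flags)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, effect=effect,
        impact=impact, damage_flags=flags, splice_region=splice_region,
        carriers=carriers or [("S1", "het")],
        external_db=external_db or {},
        cohort_allele_count=len(carriers or [("S1", "het")]),
    )


VARIANT_TSV = """chrom	pos	ref	alt	gene	effect	impact	sift	pph2_var	pph2_div	lrt	mutation_taster	mutation_assessor	provean	splice_region	in_exac	in_esp	in_tommo	carriers
chr1	1001	A	T	GENE1	missense_variant	MODERATE	D	D	D	D	D	D	D	0	0	0	0	S1:het
chr2	2002	G	C	GENE2	stop_gained	HIGH	NA	NA	NA	NA	NA	NA	NA	0	0	1	0	S2:het,S3:het
"""

MANIFEST_TSV = (
    "id\tstatus\tsex\tkaryotype\tcallable_fraction\t"
    + "\t".join(f"pc{i}" for i in range(1, 11)) + "\n"
    + "S1\tcase\tmale\tnormal\t0.97\t" + "\t".join(["0.0"] * 10) + "\n"
    + "S2\tcontrol\tfemale\tnormal\t0.96\t" + "\t".join(["0.1"] * 10) + "\n"
    + "S3\tcontrol\tmale\tXXY\t0.95\t" + "\t".join(["-0.1"] * 10) + "\n"
)

GENES_TSV = """gene	pli	mu_nonsense	mu_frameshift	mu_splice	mu_missense	mu_synonymous
GENE1	0.99	1e-06	1e-06	1e-06	1.252e-05	5e-06
GENE2	0.10	2e-06	1e-06	5e-07	8e-06	4e-06
"""


@pytest.fixture
def tiny_tables(tmp_path):
    paths = {
        "variants": tmp_path / "variants.tsv",
        "manifest": tmp_path / "samples.tsv",
        "genes": tmp_path / "genes.tsv",
    }
    paths["variants"].write_text(VARIANT_TSV)
    paths["manifest"].write_text(MANIFEST_TSV)
    paths["genes"].write_text(GENES_TSV)
    return paths


@pytest.fixture(scope="session")
def sim300():
    """A 100-case / 300-control cohort with materialized, classified variants."""
    cfg = SimConfig(n_cases=100, n_controls=300, n_genes=300, known_set_size=20, seed=11)
    cohort, truth = simulate_cohort(cfg)
    classify_variants(cohort, truth.dhs_index)
    return cohort, truth
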