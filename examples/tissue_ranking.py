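"""Tissue-expression gene-set burden scan with directional ranking.

Builds per-tissue gene sets (TPM > 10) from a simulated expression
matrix in which the case-enriched genes are overexpressed in brain
tissues, runs the covariate-adjusted burden regression per tissue set,
ranks tissues (enrichment by ascending P first, depletion by descending
P last), and contrasts brain vs non-brain ranks with a two-tailed
Wilcoxon rank-sum test. A small rank-sum P means brain-expressed gene
sets carry the case excess.
"""

import urvburden as u
from urvburden.simulate import (
    BRAIN_TISSUES, SimConfig, simulate_cohort, simulate_expression,
)

cfg = SimConfig(n_cases=150, n_controls=450, n_genes=400, known_set_size=25, seed=3)
cohort, truth = simulate_cohort(cfg)
u.classify_variants(cohort, truth.dhs_index)

expr = simulate_expression(list(cohort.genes),
                           elevated_genes=list(truth.known_genes.genes), seed=4)
ranked = u.directional_sort(u.tissue_scan(cohort, expr, variant_class="durv"))

print("top 10 tissues after directional sorting:")
for r in ranked[:10]:
    flag = "brain" if r.tissue in BRAIN_TISSUES else "other"
    print(f"  rank {r.rank:2d}  {r.tissue:20s} ({flag})  OR={r.burden.or_:.2f} "
          f"P={r.burden.p:.3g}  set size={r.gene_set_size}")

n_brain_top10 = sum(r.tissue in BRAIN_TISSUES for r in ranked[:10])
p = u.brain_vs_other(ranked, BRAIN_TISSUES)
print(f"\nbrain tissues in the top ten: {n_brain_top10}/10")
print(f"brain vs other rank-sum P = {p:.4f}")
print("with the planted brain overexpression the brain tissues should cluster")
print("near the top and the rank-sum P should fall below 0.05.")
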