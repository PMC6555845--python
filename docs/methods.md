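# Methods and design notes

This note records the statistical models behind each component, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where more than
one reasonable option existed.

## Rarity model and count QC

A variant is *ultra-rare* when it is absent from every selected external
population panel and carried by exactly one qualifying allele in the
full cohort. Qualification is per chromosome class: autosomal and
pseudoautosomal heterozygotes; X-non-PAR heterozygotes in females and
47,XXY individuals; X-non-PAR homozygotes in (non-XXY) males and Y
homozygotes in males and 47,XXY individuals, both read as hemizygous.
`hemi` and `hom` are interchangeable on the sex chromosomes.
Doubletons and tripletons are the 2- and 3-allele bins of the same
partition. Allele counts are taken over the *pre-QC* cohort; outlier
individuals are then removed from analysis while the rarity labels
stand, matching the stated order of operations. Mitochondrial and
unplaced contigs are excluded with a warning.

Per-individual coding URV counts are screened with a two-sided
Smirnov–Grubbs test. The statistic G = max|xᵢ − x̄|/s maps to a
t-statistic via G = ((n−1)/√n)·√(t²/(n−2+t²)); the two-sided P is
2n·P(T₍n−₂₎ ≥ t), capped at 1. Default α = 0.001. The test is applied
iteratively (remove the most extreme value, retest) because a single
threshold removed multiple individuals in the motivating design; a
`iterate=False` flag gives the single-pass variant. The decision uses
only the count vector, never phenotype.

## Functional taxonomy

Leaf classes are mutually exclusive: null (stop-gained, frameshift,
splice donor/acceptor, stop-lost), CD missense (all seven predictors
affirmatively damaging — an NA in any predictor disqualifies), other
moderate (including protein-protein-contact and start-lost calls
reclassified out of the HIGH-impact group, and inframe indels, which
usually lack predictions and therefore land here), splice-region
synonymous (within 3 bp of an exon end that abuts an intron), DHS
synonymous (inside a DNase-hypersensitive-site interval index), other
synonymous, noncoding. A synonymous variant that is both splice-region
and DHS is assigned to splice-region by default; the reverse precedence
is selectable (`ClassifyConfig(sr_before_dhs=False)`) because published
subtotals of the three synonymous subclasses can overlap and the
assignment rule is a genuine free choice. Positions are 1-based
(VCF convention); interval inputs are 0-based half-open (BED), converted
exactly once at query time.

## Burden regression

For a class (optionally restricted to a gene set and a case subset) the
per-individual count x is entered into
logit P(case) = β₀ + β₁x + γ'z, with z = (sex, callable fraction,
PC1–PC10). Fitting is Newton maximum likelihood (statsmodels), tolerance
1e-8, 100 iterations, BFGS fallback; non-convergence is flagged, not
raised. Inference on β₁ is the Wald z-test with exp(β₁ ± 1.96·se) as the
95% CI — the convention matching standard logistic output. When every
carrier lies in one outcome class (complete separation) the count of the
first control in lexicographic id order is incremented by one, the model
refit, and the result flagged `p_is_upper_bound` — the pseudo-count makes
the reported P conservative for the enrichment direction. Which control
receives the pseudo-count is statistically immaterial (any single
control changes the 2×2 the same way); the lexicographic rule just makes
it deterministic. Bonferroni (min(1, m·p)) and Benjamini–Hochberg
(step-up with monotonicity) run over the analysis manifest that fixes m.

## Gene collapsing and permutation overlap

Per gene, the 2×2 table of case/control carriers of ≥1 damaging URV is
tested with the two-tailed Fisher exact test, two-sidedness by the usual
"probability mass ≤ observed" rule. Reported ORs use the Haldane 0.5
continuity correction on zero cells. Exome-wide significance is
P < 0.05/20,000; the nominal band is 2.5×10⁻⁶ ≤ P < 0.05. Genes whose
carriers are all excluded drop out (they can never be significant).

The overlap test permutes case/control labels (group sizes preserved
exactly), re-runs the scan, and records the fraction of nominal genes in
the reference set; iterations with no nominal gene contribute fraction
0. The empirical P is the plain exceedance fraction (#null ≥ observed)/n,
reported as "< 1/n" at zero exceedances — not the (r+1)/(n+1) variant,
so a zero can occur and is reported as a bound. Randomness comes from
one master seed with per-iteration child streams
(`SeedSequence.spawn`), so equal seeds give identical results. Fisher
P-values are memoized on (case-carrier, total-carrier) pairs, which is
what makes 10⁴ permutations practical.

## DNM enrichment

For a gene with per-haploid consequence rates, μ_null = μ_nonsense +
μ_frameshift + μ_splice and μ_CDmissense = μ_missense·(203/1252), the
fraction of missense de novo mutations that are consensus-damaging in
unaffected-sibling control trios. λ = (μ_null + μ_CDmissense)·2·n_trios;
the test is the Poisson upper tail P(X ≥ k) (scipy survival function,
exact for the λ ≤ 1 regime used here; λ = 0 gives P = 0 for k ≥ 1, and
k = 0 gives P = 1). Corrections multiply by the testable-gene count
(genes with ≥1 damaging URV, by default) or by the disease-subtype
count, capped at 1 only. `invert_lambda` solves P(X ≥ k; λ) = p by
Brent's method, bracketed around the leading-order seed λ ≈ (k!·p)^{1/k},
relative tolerance 1e-10; it lets a published tail probability be
converted into an expected count and transferred between cohort sizes
(λ scales linearly in n_trios; for small λ the k=3 tail then scales
approximately cubically).

## Tissue ranking

Gene sets are "TPM strictly > threshold" (default 10) per tissue;
specificity-index gene sets are accepted as precomputed inputs instead.
Each set reuses the burden regression (same covariates) on damaging
counts restricted to the set. The directional order is: enriched tissues
(OR > 1) by ascending P, then OR exactly 1 (placed at the end of the
enriched block — such a tissue carries no enrichment evidence), then
depleted tissues by descending P; ties break on tissue name, so the
order is total and input-order invariant. The brain-vs-other contrast is
the two-tailed Wilcoxon rank-sum on the resulting ranks: exact
distribution when both groups have ≤ 25 members (ranks are a permutation,
so ties cannot arise), normal approximation with continuity correction
otherwise.

## Power

The test of interest is the two-sided Wald z-test on the slope of a
logistic regression with a normally distributed predictor. The effect is
the OR for a 1-SD increase, so on standardized X the slope is
β₁ = ln(or_1sd); the baseline probability p₀ fixes the intercept via
β₀ = logit(p₀); correlation with other covariates inflates the slope
variance by 1/(1−R²). The slope variance v₁ is taken from the Fisher
information of the two-parameter model integrated over X by 201-point
Gauss–Hermite quadrature. Default power is
Φ(−z_{α/2} + |β₁|√(n(1−R²))/√v₁) + Φ(−z_{α/2} − ·); a classical
two-variance form with the null variance evaluated at the marginal event
rate is available (`variance="null"`). The two differ by under two
percentage points at the parameter sets of interest; the default was
validated against a Monte-Carlo simulation of the fitted model (within
±3 points) and reproduces the reference calculator's printed 93/75/52%
triplet at α = 0.05/0.0056/0.00076 to within a point. The pooled SD
helper is √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)).

## Synthetic-data generator

`simulate_cohort` emulates the marginal structure the analysis assumes:

* **Counts.** Per-individual coding totals are drawn from
  Normal(54.4, 8.2) (rounded, clipped at 0) and split multinomially
  across the six coding leaves with proportions fixed by the study-scale
  totals (null 12,032; CD missense 12,337; other moderate 96,726; DHS
  synonymous 11,247; splice-region synonymous 1,277; other synonymous
  35,395 of 169,014). Drawing the total first, rather than independent
  per-class Poissons, is what reproduces the stated SD of 8.2 (a Poisson
  total would have SD √54.4 ≈ 7.4). Noncoding counts are Poisson with
  mean 42,974/3,109.
* **Genes.** Lognormal gene lengths set both variant-assignment weights
  and mutation rates (missense 1.1e-5 per mean-length gene, scaled);
  pLI is a bimodal Beta mixture and the known disease-gene set is the
  top-pLI slice (58 genes at default scale).
* **Effects.** Case status is prospective-logistic on the damaging
  counts: default per-URV ORs 1.09 (null) and 1.06 (CD missense) outside
  the known set — the scale of genome-wide effects reported for this
  design — and 4.0/3.0 inside it, plus weak sex and PC1 effects. The
  intercept is solved by bisection so the expected case fraction matches
  the design (743/3,109 at default scale); realized case counts are
  binomial around that.
* **Variants.** Each counted variant is materialized as a singleton
  record whose annotations reproduce its intended class under the
  classifier (seven damaging flags for CD missense, a spoiled flag for
  other moderate, positions inside the per-gene DHS window for DHS
  synonymous, the splice-region bit for splice-region synonymous).
  Extra doubleton/tripleton variants (study-scale ratios 45,832 and
  20,786 per 169,014 singletons) and a 10% external-panel-flagged
  fraction exercise the rarity partition.
  `materialize_variants=False` skips record creation for count-level
  work (calibration at many replicates).
* **Trios and expression.** `simulate_trio_dnms` draws per-gene Poisson
  counts at λ·fold for enriched genes; `simulate_expression` draws
  lognormal TPM over 53 tissues (13 brain) and multiplies the expression
  of designated genes by `brain_bias` (default 4.0, at which the planted
  brain signal is detected by the rank-sum contrast in ≥90% of seeds at
  moderate cohort scale) in brain tissues.

What the generator does **not** emulate: sequence context (alleles are
placeholder bases), linkage disequilibrium, population substructure
beyond Gaussian PCs, relatedness, batch effects in coverage, X-linked
burden variants (generated variants are autosomal; the X-chromosome
rules are exercised by hand-built fixtures), and variant-level
correlation between deleteriousness and allele frequency. Passing tests
therefore certify the statistical machinery under the assumed sampling
model, not robustness to those real-data complications.

## Test design and problem sizes

Null calibration uses 200 count-level replicates (120/360 individuals)
for the burden regression, five materialized null cohorts (~1,500
gene-tests) for the collapsing scan, ten independent null cohorts at 50
permutations each for the overlap test, and ~2×10⁶ simulated gene-tests
for the DNM model. Parameter recovery runs 150 replicates per planted OR
(1.05, 1.10, 1.5) at 375/1,125 individuals, checking ~95% CI coverage
and unbiasedness of the log-OR. These sizes were chosen so the full
suite completes in a few minutes on one core while keeping binomial
noise on coverage estimates below ~2%. The DNM recovery property uses a
fixture whose target gene sits at the extreme of per-gene mutability
(per-haploid damaging rate ~3×10⁻⁴): at typical rates a 50-fold
enrichment over 237 trios yields an expected count well below one and no
test could recover it reliably.

## Known limitations

* Wald inference can be anti-conservative for very sparse counts; a
  likelihood-ratio alternative is not currently exposed.
* The pseudo-count separation fix is a reporting convention, not an
  estimator; Firth regression would be the principled alternative and is
  out of scope.
* The permutation overlap test reuses the nominal band of the real-label
  scan; reference sets that overlap the excluded-genes list are the
  caller's responsibility.
* Exact rank-sum P switches to a normal approximation above 25 tissues
  per group; with the standard 53-tissue panel the exact path is always
  taken.
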