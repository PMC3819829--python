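# Methods

## Model and procedure

The package tests, for every (SNP, transcript, phenotype) trio, whether the
SNP's effect on the phenotype is transmitted through the transcript. With
gene dose X (0/1/2 copies of the alternate allele), transcript level M and
phenotype Y, the classical four regressions are

1. Y = α₁ + β₁X + ε₁ (total effect),
2. M = α₂ + β₂X + ε₂,
3. Y = α₃ + β₃M + ε₃,
4. Y = α₄ + β₄M + β₅X + ε₄,

with εₖ ~ N(0, σₖ²) independently. The quantity of interest is the indirect
effect β₂β₄. Steps 1 and 3 are computable (`simple_regression`) but are
deliberately **not** used as significance gates: the causal-steps screen
does not itself test the indirect pathway and costs power against
trans-acting signals, so the trio criterion is the product test alone.
An optional causal-steps gate can be imposed by the caller by filtering on
the step-1/step-3 fits.

Two tests of β₂β₄ are provided:

* **Analytic (default).** The multivariate-delta-method standard error
  σ = sqrt(β₂²σ₄² + β₄²σ₂²) and Δ = β₂β₄/σ referred to N(0, 1), two-sided.
* **Permutation.** Y is permuted and Eq (4) refitted for β₄⁺; M is
  independently permuted and Eq (2) refitted for β₂⁺; the observed product
  is compared two-sidedly to the B null products with the add-one rule
  p = (1 + #{|β₂⁺β₄⁺| ≥ |β₂β₄|})/(B + 1), so p ≥ 1/(B+1) and ties never
  produce p = 0.

The two tests are genuinely different procedures, not approximations of one
another. The permutation null has scale ≈ σ₂σ₄ (a product-normal), while
the analytic test standardizes by sqrt(β₂²σ₄² + β₄²σ₂²); when one path is
strong and the other moderate the permutation p is far smaller than the
analytic p. This is the permutation test's documented extra sensitivity,
and users should pick one criterion and report it, not mix them. The
default is the analytic test with B = 0 permutations; permutation is
applied (configurably) only to trios passing the analytic screening cutoff,
because a raw B large enough to resolve p ≈ 10⁻⁵ genome-wide is
computationally symbolic.

Under partial nulls (β₂ = 0, β₄ ≠ 0) the analytic test is at most nominal
and under the complete null it is conservative — the familiar behaviour of
this statistic — which the test suite checks by simulation.

## Genome-wide scan

`scan_trios` fits Eqs (2) and (4) for every SNP × probe pair using
closed-form centered cross-products, vectorized across probes within each
SNP. Missing data are handled complete-case **per trio**: a sample enters a
pair only if its dose, probe value and phenotype are all observed. Pairs
with fewer than 5 complete cases, zero dose variance, or a collinear
(M, X) design are emitted as NaN (and never counted significant).
Processing is chunked in SNP blocks only for streaming; no state crosses
blocks, so output is bitwise independent of the block size (tested at block
sizes 1, 7, 64). Permutation seeds derive from (run seed, SNP index, probe
index), keeping results chunk- and order-invariant.

The eQTL scan (`eqtl_scan`) is the same step-2 machinery with a two-sided
t-test on n−2 degrees of freedom. A pair is cis when SNP and probe share a
chromosome and lie within a 1 Mb window (inclusive bound; configurable),
trans otherwise, unknown when annotation is missing.

## Quality control

Samples with genotype call rate below 95% are removed first; SNP statistics
are then computed on the remaining samples. SNPs are removed when call rate
< 95%, when the Hardy–Weinberg test is significant at 0.001, or when MAF
< 10%. All thresholds are strict inequalities ("less than"), so values
exactly at a threshold pass. The HWE test is the exact conditional test:
given the observed allele counts, the conditional probability of each
attainable heterozygote count h is proportional to 2ʰ n!/(n_rare-hom! h!
n_common-hom!), and the p-value sums the probabilities of tables no more
probable than the observed one (plain, not mid-p; computed in log space
with a 1e-12 relative tie guard). A 1-df chi-square alternative is
available via configuration; the exact test is the default because it is
well defined at every MAF and sample size the pipeline encounters.

## Normalization

Phenotype and each expression probe are residualized on intercept + age +
sex by OLS (two-level sex labels are mapped to 0/1; constant covariate
columns are dropped with a warning rather than failing), then mapped to
standard-normal quantiles through average-tie ranks at (r − 0.5)/n — the
Blom offset (r − 3/8)/(n + 1/4) is available. Adjustment precedes
normalization, once each. The rank-based transform is read as the standard
quantile (inverse-normal) normalization for quantitative traits; a
coarse 4-bin "quartile" binning would be a different and strictly less
informative procedure and is not offered.

## By-chance FDR

For a scan of T = (#SNPs × #probes) tests at threshold α, the expected
number of significant results under a global null is Tα, and
FDR = Tα / #observed-significant. With the published platform counts
(214,399 and 471,394 SNPs, 30,128 probes, α = 10⁻⁵, 389,573 and 1,214,416
significant trios) this yields 16.6% and 11.7% to one decimal. Note the
numerator treats all T tests as null, so the estimate is slightly
conservative when true signals exist. The scan summary counts significant
trios, distinct SNPs and distinct probes.

## Hotspots

A hotspot is a SNP whose count k of significant probes (at the pair cutoff)
reaches `hotspot_min_probes` (default 20). Enrichment is the exact binomial
upper tail P(K ≥ k | n_probes, p0) with p0 defaulting to the nominal pair
cutoff (10⁻⁵) — a data-driven p0 (global significant fraction) can be
supplied instead — Bonferroni-multiplied by the number of SNPs in the scan
(the whole tested family, not just candidate hotspots) and capped at 1.
The enrichment score is −log10 of the corrected p (p floored at 1e-300 to
keep the score finite). The overlap step joins significant mediation trios
against hotspot SNP membership and reports (trios, distinct SNPs, distinct
mediator probes).

## Synthetic data

`SimulationSpec` describes a cohort-shaped dataset: default 200 samples
(the scale at which genotype, expression and activity data overlap in a
liver cohort), SNPs with MAFs uniform on (0.1, 0.5] in Hardy–Weinberg
proportions across 22 autosomes, Gaussian expression noise (σ = 1), a 2%
genotype missing rate, age ~ U(20, 80) years and sex ~ Bernoulli(0.5) with
modest phenotype effects (0.2 SD per SD of age; 0.4 for sex) so covariate
adjustment is exercised non-trivially. Planted mediated trios, hotspot
SNPs and direct effects are linear-additive on the *true* (pre-masking)
doses; the analyst sees the masked genotypes. Everything is
bit-reproducible from (spec, seed), and the returned truth record lists the
planted pairs so true/false positives — and hence an empirical FDR — can
be computed for any scan output.

Planted-signal test scenarios draw MAFs from (0.2, 0.5): an effect size
carries its nominal detectability only at common-variant frequencies, and
the point of those scenarios is to test recovery of a well-powered planted
architecture, not power at the QC boundary. Null-calibration scenarios
keep the default range.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, array batch/probe effects, non-Gaussian expression distributions,
population structure or relatedness. Passing tests therefore demonstrate
correctness of the statistics under the model's own assumptions, not
robustness to real-array artifacts.

## Numerical choices and problem sizes

* Regression via centered cross-products in float64; agreement with a
  normal-equation solver is held to 1e-10 relative in tests.
* Two-sided tests throughout; genotype enters additively (gene dose), no
  dominance coding.
* Simulation-based tests run at desk scale: calibration at 1000–2000
  replicates, recovery at 100–500 seeds, null-hotspot checks at 500 SNPs ×
  1000 probes × 20 seeds. Monte-Carlo tolerances are stated as 2 standard
  errors of the estimate in question.
* TSV outputs print floats at 10 significant digits; round-trips preserve
  records to that precision.

## Known limitations

* Mediation here is associational: the scan assumes the causal ordering
  X → M → Y and cannot distinguish it from reactive or independent models.
* The by-chance FDR is a global-null expectation, not an adaptive FDR.
* The hotspot binomial treats probes as independent; co-expressed probe
  clusters inflate enrichment for a truly associated SNP.
* VCF input supports biallelic genotype records only (multi-allelic records
  are skipped with a warning); dosage-format (non-integer) genotypes and
  PLINK binary files are out of scope.
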