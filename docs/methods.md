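# Methods

This note documents the statistical procedures implemented in `finelocus`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic cohort generator does and does not emulate, and the package's
known limitations.

## Setting

The package targets the dissection of a single disease-associated locus in
a case-control design. The concrete system is the Paget's-disease locus at
14q32: a GWAS tag SNP (rs10498635, intronic, no predicted function) in
near-perfect LD with a common missense variant in *RIN3* (p.R279C,
rs117068593), and a panel of rare missense/regulatory variants that sit
almost entirely on the common risk-haplotype background. Inputs are
per-cohort allele-count tables (the publishable summary form), optional
individual-level genotypes (GT-only VCF subset) or imputed dosage matrices,
and per-variant pathogenicity-predictor panels. Alignment, variant calling,
imputation itself, and running the upstream predictors are all out of
scope; their outputs are consumed as inputs.

## Contingency statistics

Every allelic test operates on the 2×2 table

|          | alt | ref |
|----------|-----|-----|
| cases    | a   | b   |
| controls | c   | d   |

with allele denominators always 2 × individuals. Printed percentages in
input tables are never trusted; frequencies are recomputed from counts.

* **Odds ratio and CI.** OR = ad/bc with the Woolf log-interval. The
  interval method is a package choice (the source tables do not state one);
  it reproduces the published intervals to rounding on every
  reconstructible row. Any zero cell triggers the Haldane–Anscombe +0.5
  correction on all four cells, flagged in the result object.
* **χ² allelic test.** Pearson statistic with 1 df, no Yates correction —
  the published p-values for the common variants are consistent with the
  uncorrected statistic (e.g. counts 54/492 vs 129/758 give χ² = 8.72,
  p = 3.2×10⁻³ against a printed 3.1×10⁻³). Zero margins are errors.
* **Fisher's exact test.** Direct enumeration over the feasible range of
  cell *a* at fixed margins, log-pmf via `gammaln`. The two-sided p-value
  follows the point-probability rule — the sum of probabilities of all
  tables whose point probability is at most that of the observed table,
  with relative tolerance 1e-12 for floating-point ties. A table with a
  monomorphic column has p = 1 and an undefined OR (returned as NaN).
  The implementation is verified exhaustively against an independent
  hypergeometric-summation oracle for all tables with row margins ≤ 60
  and against `scipy.stats.fisher_exact` on random tables.
* **Combination.** `pool` sums cells then applies the auto-selected test
  (χ² when all expected cells ≥ 5, else Fisher); `cmh` computes the
  Cochran–Mantel–Haenszel common OR and 1-df statistic via statsmodels.
  CMH is the default for stratified panels because reference cohorts with
  different base frequencies can produce Simpson-style artefacts under
  naive pooling. The published all-cohorts combined OR (0.64) is not
  reconstructible from printed inputs — the cohort composition of that
  combination is not stated — and is treated as qualitative only.

## Rare-variant burden

Variants qualify when their folded minor allele frequency is strictly
below the threshold (default 1%) in cases **or** in the chosen control
panel; variants absent from the panel count as unobserved there (0 alt
alleles over the full panel denominator). Qualifying alt alleles are pooled
into a single table and tested exactly.

Two counting units are provided. The **carrier** unit (default) treats
each pooled alt allele as one carrier individual over the individual
denominator — exact while no individual carries two rare alleles, which
cannot be verified from a summary table and is documented as an
approximation. It is the unit under which the published pooled counts
(25 case alleles / 246 cases vs 127 / 4300 panel individuals) reproduce
the published OR 3.72; the **allele** unit gives 3.57 on the same counts.
A caveat found while reconstructing: the published p for this comparison
(8.9×10⁻¹⁰) matches a χ²-style computation on the carrier table
(9.5×10⁻¹⁰) rather than the Fisher p (3.8×10⁻⁷); the package reports the
exact p and asserts only the OR against the published value.

No frequency weighting and no variance-component (SKAT-style) test is
offered — the implemented procedure is plain collapsing.

## Haplotypes, LD, and phase posterior

Haplotype frequencies over k ≤ 8 hard-genotyped loci are estimated by the
classical EM algorithm under HWE: the E-step distributes each individual's
genotype over its 2^(m−1) compatible haplotype pairs (m = heterozygous
loci) proportionally to current pair probabilities; the M-step re-estimates
frequencies from expected counts. Initialization is uniform so results are
deterministic; the log-likelihood is asserted non-decreasing at every
iteration; convergence is a max frequency change below 1e-8 (default).
Missing genotypes drop the individual for the estimation; monomorphic loci
simply leave their alternative haplotypes at frequency zero.

Two-locus LD uses the ALT–ALT convention: D = p₁₁ − p₁·p·₁,
D′ = |D|/D_max, r² = D²/(p₁·p₀·p·₁p·₀). The published backbone
distribution (risk haplotype 0.812, complement 0.182, recombinants 0.004
and 0.002) evaluates to D′ = 0.987, r² = 0.961, matching the published
0.98 / 0.96.

Haplotype case-control association is reconstructed from published
frequencies as a 2×2 of haplotype counts with denominators 2n chromosomes.
The cells are kept **real-valued** (frequency × 2n) rather than rounded to
whole haplotypes: rounding discards the only information available (the
printed frequencies) and shifts the reconstructed OR for the 86.4% vs
81.2% comparison from 1.471 to 1.467; the real-valued reconstruction
preserves the frequency-implied OR exactly. An `integer_counts=True`
option restores whole-count behaviour for users who want a literal count
table.

The fraction of rare-variant alleles on a designated haplotype background
is estimated by posterior phase assignment: EM over backbone loci plus the
rare variant, then each carrier's compatible phases weighted by their
posterior probability under the fitted frequencies. A single carrier
heterozygous at all backbone loci is genuinely phase-ambiguous — the
posterior then follows the HWE prior, which can place an isolated rare
copy on the more common complementary background. Information accrues
across carriers; the packaged calibration pools all rare variants of a
simulated cohort and recovers the generating 96% placement within
Monte-Carlo error.

## Dosage logistic regression

`logit P(case) = β₀ + β₁·dose (+ β₂·dose_cond)` is fitted by iteratively
reweighted least squares (convergence max|Δβ| < 1e-8, cap 100 iterations).
Fractional imputed dosages enter directly, which is the standard device
for propagating imputation uncertainty into the test. Wald CI and p-value
are reported for exp(β₁). Failure modes are explicit errors, never silent
estimates: rank-deficient designs (constant dosage, conditioning on a
perfect sample proxy — the conditional-analysis signature of a fully
absorbed signal) raise a singular-design error; complete separation is
detected when the fitted probabilities match the outcomes to within 1e-6,
and iteration exhaustion raises a convergence error. No covariates beyond
dosages are supported; ancestry correction is out of scope.

Calibration: on large HWE samples with hard genotypes the per-allele
logistic OR agrees with the allelic contingency OR within 5%, and the Wald
test's null type-I error is ≈5% at α = 0.05 over 1000 replicates of
n = 2000 (both checked in the test suite and recomputed by the acceptance
script).

## QC filters

Sequencing-stage QC drops sites with quality < 20 (Phred), coverage < ×5,
and indels; the thresholds are strict less-than exclusions (equality
passes), applied per site. Records lacking the fields a requested filter
needs raise rather than passing silently. Post-imputation QC drops
variants with folded MAF < 0.01 (from mean dosage / 2) or imputation
r² < 0.3. Both filters are idempotent.

## Pathogenicity scoring

One point per satisfied criterion: SIFT damaging; PolyPhen-2 possibly or
probably damaging; Condel deleterious; MutationTaster disease-causing;
GERP strictly > 2.0; Grantham distance strictly > 50 (looked up in the
embedded published 20×20 matrix when not supplied; symmetric, zero
diagonal, range 5–215). Missing predictor outputs score zero and are
tallied in `n_missing` rather than raising — real panels routinely have
tools that return no call. Mapping raw predictor scores to verdicts is the
upstream tools' job. ΔΔG strictly greater than 1.6 kcal/mol classifies a
substitution as severely destabilizing. The published per-variant composite
scores ship in the packaged table as documentation; they cannot be
regenerated end-to-end here because the per-tool verdicts behind them were
not published.

## Synthetic cohort generator

The generator emulates the locus architecture the analysis assumes, so
every pipeline stage is testable without external data:

* two backbone loci with haplotypes CC/TT/CT/TC at control frequencies
  0.812 / 0.182 / 0.004 / 0.002 (risk haplotype CC; C coded as REF);
* rare variants (default 15 at population AF 0.2%, matching the scale of
  the observed rare-variant panel) placed per allele copy, independently,
  on risk vs non-risk backbone copies with probability 0.96 vs the
  complement — the simplest mechanism consistent with the observed
  placement fraction;
* a logistic disease model on allele counts: log-odds = logit(prevalence)
  + ln(OR_hap)·(risk-haplotype copies) + Σ ln(OR_v)·(rare copies), with
  defaults OR_hap = 1.48, baseline prevalence 0.02 (the upper end of PDB
  prevalence in older European populations);
* retrospective ascertainment by rejection sampling until the requested
  case and control counts are met, with a bounded draw budget.

Everything flows through one seeded generator; equal seeds give identical
cohorts. The emitted truth object carries phased haplotypes, rare-allele
placements, per-individual case probabilities and realized counts, which
the tests check against the unphased matrix exactly.

What the generator does **not** emulate: recombination within the locus
beyond the fixed recombinant haplotype frequencies, population structure
and relatedness, genotyping/imputation error (dosage noise must be added
by the caller), sequencing depth or call errors, dominance or interaction
effects, and linkage of the rare variants to each other beyond sharing the
backbone. Passing tests therefore demonstrate the statistics are computed
correctly under the stated model, not robustness to those real-data
complications.

## Monte-Carlo study sizes and numerical choices

The packaged calibration studies use: 200 cohorts of n = 2000 for EM
frequency recovery (mean absolute error < 0.01 per haplotype); 200
replicates of 500 cases / 500 controls for burden CI coverage; 1000
replicates of n = 2000 for logistic null calibration; an exhaustive
enumeration sweep over all 2×2 tables with row margins ≤ 60 for the exact
test. For coverage, "truth" is the generative model's marginal
carrier-copy odds ratio computed in closed form (mixture-binomial copy
distribution inverted by Bayes' rule, 4.74 under the default conditions)
rather than the per-allele parameter 4: collapsing estimates the marginal
carrier effect, which under a multiplicative per-allele model exceeds the
per-allele OR (double-carriers contribute OR 16), and conflating that
estimand difference with interval calibration would make the coverage
check meaningless.

Tie-breaking and degenerate-input conventions: Fisher ties at relative
1e-12; EM monotonicity tolerance 1e-9 on the log-likelihood; haplotype
association refuses frequencies of exactly 0 or 1; burden carrier counts
exceeding the individual count raise; dosages outside [0, 2] are input
errors; missing genotypes are dropped pairwise, never imputed.

## Known limitations

* The all-cohorts combined association (OR 0.64) and the imputed-cohort
  statistics (imputed p = 5.7×10⁻⁶, r² = 0.96 on real genotypes) require
  individual-level data that is not public; the package reproduces the
  desk-scale numbers and substitutes simulation-based calibration for the
  rest.
* The carrier burden unit is an approximation bounded by the
  one-rare-allele-per-individual assumption.
* EM phase assignment assumes HWE; case-control ascertainment distorts
  HWE slightly, which biases the background-placement posterior by an
  amount small relative to Monte-Carlo error at the packaged study sizes.
* The haplotype-association reconstruction inherits the rounding of the
  published frequencies (two reconstructions, 1.47 real-valued vs 1.467
  integer-rounded, against a published 1.48).
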