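# Methods

## Model and assumptions

The package implements summary-level two-sample Mendelian randomization: genetic
variants serve as instruments for an exposure, and causal effects are estimated
from the per-SNP exposure and outcome associations of two non-overlapping GWAS.
The three classical IV assumptions apply (instruments associate with the
exposure; are independent of confounders; affect the outcome only through the
exposure), plus the two-sample requirements that the cohorts not overlap and
come from comparable populations. Binary outcome associations are treated as
log-odds throughout, so OR = exp(beta) exactly.

Two-step mediation MR decomposes the total effect β_EO of an exposure on the
outcome into an indirect part β_EM·β_MO running through a mediator and a direct
remainder. The proportion mediated is (β_EM·β_MO)/β_EO. This assumes no
exposure–mediator interaction on the outcome; that assumption is not testable
from summary data and is documented rather than checked. The SE of the
proportion uses the first-order delta method with the three component estimates
treated as independent — customary for non-overlapping two-sample designs. A
proportion outside [0, 1] (sign-discordant chain) is reported with a flag, not
suppressed: divergence between univariable and mediation-model estimates for
the same trait is a real phenomenon and both are reported without
reconciliation.

MVMR regresses outcome betas on the matrix of exposure betas (no intercept,
weights 1/se_out²); each coefficient is a direct effect conditional on the
other exposures. Colocalization uses per-SNP Wakefield approximate Bayes
factors and the standard five-hypothesis posterior (at most one causal variant
per trait per locus), entirely in log space.

## Harmonization rules

Effect alleles of the outcome are aligned to the exposure's: matching
orientation is kept, swapped orientation negates the outcome beta and
complements its allele frequency, and strand-complement labels are complemented
first. Palindromic variants (A/T, C/G) are label-aligned the same way and then
kept only when both allele frequencies are present, fall on the same side of
0.5, and lie outside [limit, 1−limit] with limit 0.42 (configurable); a missing
frequency on either side drops the variant (conservative). Harmonization is
idempotent and a double flip of the outcome file is an identity — both are
property-tested against the simulator, which records the true orientation of
every SNP.

## Instrument selection

Filters run in a fixed order: p-value threshold, then allele frequency, then
instrument strength, then LD clumping. Defaults mirror the data sources the
pipeline is designed for: suggestive p < 1e-5 for microbial-abundance
exposures, genome-wide p < 5e-8 for metabolite and disease instruments, minor-
allele frequency > 0.01, and per-SNP F = (beta/se)² ≥ 10 (the single-SNP
approximation; no individual-level data are assumed). The frequency filter is
applied to the minor-allele side, since allele labeling is arbitrary. Clumping
is greedy on (p-value, snp_id) order: the best remaining SNP is kept and all
SNPs within 10,000 kb on the same chromosome with r² ≥ 0.001 against it are
discarded; ties break lexicographically so the retained set is independent of
input row order. The LD matrix is an input (first line SNP ids, then rows of
r); without one, SNPs are assumed pre-clumped and passed through with a notice.
SNPs absent from a supplied matrix are treated as independent with a warning.

## Estimator conventions

* IVW: multiplicative random effects by default — the fixed-effect SE is
  multiplied by sqrt(Q/(J−1)) when that exceeds 1, and never shrunk below the
  fixed-effect value. Fixed-effect inference is available by flag. Inference is
  normal.
* Cochran's Q is computed in the algebraically equivalent residual form
  Σ(β_yj − β·β_xj)²/σ_yj², which avoids dividing by near-zero exposure betas;
  p from chi-square with J−1 df.
* MR-Egger orients exposure betas non-negative before the weighted fit, uses
  the estimated (unfloored) residual variance, and t inference with J−2 df —
  with these choices the intercept p-value is exactly uniform under the null,
  which the test suite verifies over 500 replicates. Heterogeneity about the
  Egger fit (Rücker's Q′) uses J−2 df.
* Wald ratio SE is first-order delta method by default; the second-order
  variant (adding β_y²σ_x²/β_x⁴) is available by flag and is never smaller.
* MVMR covariance comes from the weighted-least-squares normal equations with
  the residual variance floored at 1, matching the IVW random-effects
  convention; an exposure whose betas are exactly zero at every SNP is
  reported as beta 0 with NaN SE and the remaining exposures are fit on the
  reduced design; rank deficiency among informative exposures raises a
  collinearity error naming the offending traits.
* Method routing in the pipeline follows the instrument count: 1 → Wald ratio,
  ≥ 2 → IVW, ≥ 3 adds MR-Egger as sensitivity. Screening significance is the
  raw p < 0.05, reflecting the practice of the study designs this emulates;
  Benjamini–Hochberg q-values are annotated alongside per screening family but
  do not drive the flags.

A consequence of flooring the random-effects scaling, computed analytically by
integrating over the null distribution of Q: the null rejection rate of IVW at
nominal 0.05 is ≈ 0.039–0.041 and 95% CI coverage ≈ 0.959–0.961 for 10–20
instruments. The calibration tests assert bands containing these values
([0.03, 0.07] for the type-I rate; [93%, 97%] for coverage).

## Colocalization choices

Priors default to p1 = p2 = 1e-4, p12 = 1e-5; prior effect SDs default to 0.15
for quantitative traits and 0.2 for binary (log-odds) traits. Loci are windows
of ±500 kb around a user-supplied anchor position; gene models are not bundled.
All five posteriors are always reported; the decision flag is PPH4 > 0.75. All
hypothesis sums use log-sum-exp and remain finite for |z| of 50 and beyond.

## The synthetic-data generator

`simulate()` emulates the statistical structure of the intended data sources: a
16S microbiome-scale exposure GWAS (n = 18,340), a plasma-metabolite GWAS
(n = 7,824) and a rare binary outcome (n = 408,241, case fraction
1,086/408,241) on the log-odds scale. Per SNP, minor-allele frequency is
uniform on (0.05, 0.5); instrument effects on the exposure are N(0, γ_sd²) with
γ_sd = 0.08 by default (single-SNP F in the tens, the strength reported for
microbial and metabolite instruments); mediator-specific instruments are
N(0, δ_sd²) with δ_sd = 0.12 so the mediator→outcome leg has genome-wide-
significant instruments of its own — without them that leg of two-step MR is
not estimable. True effects follow the chain: mediator = β_EM·γ + δ +
pleiotropy, outcome = (β_direct + β_EM·β_MO)·γ + β_MO·δ + pleiotropy. Observed
betas add N(0, se²) noise with se = 1/sqrt(2p(1−p)n) for quantitative traits
and 1/sqrt(2p(1−p)·n·φ(1−φ)) for the binary outcome — effects are simulated
directly on the summary scale rather than via individual-level logistic
sampling, which keeps the generator exact and fast. Noise z-scores share a
compound-symmetric correlation inside consecutive LD blocks, and the returned
LD matrix is the corresponding block matrix. Allele labels, orientations and
(for non-palindromic pairs) strand are randomized per trait and recorded in the
ground-truth object. Directional pleiotropy is applied relative to the
exposure-increasing allele — the frame in which MR-Egger's intercept is
defined — while balanced pleiotropy is sign-agnostic; pleiotropy acts on
mediator and outcome only (exclusion-restriction violations).

What the generator does **not** emulate: genome-wide realistic LD maps,
allele-frequency estimation error, sample overlap between cohorts, population
stratification, winner's-curse from discovery-sample instrument selection, and
non-normal effect-size distributions. Passing calibration tests therefore shows
the estimators are correct under their stated assumptions, not that real-data
biases are absent.

`simulate_mvmr()` builds a joint multi-exposure design with block-wise
instruments; its effect scale (0.125) is chosen so simulated instrument
strength matches metabolite-GWAS instruments (median F ≈ 49 at n = 7,824). Even
at that strength, measurement error in the exposure betas leaves a visible
weak-instrument attenuation (~1 SE on a large coefficient across replicates) —
an inherent property of regression-based MVMR, retained rather than hidden.

## Numerical and testing choices

Replicate counts in the calibration tests (500 for coverage/Q/Egger-null, 250
screens × 20 exposures for the null rejection rate, 500 MVMR and 200 mediation-
chain replicates) use small per-replicate panels (10–30 SNPs) so the whole
suite runs in well under a minute per property; these sizes give binomial
standard errors a few times smaller than the asserted bands. All randomness
flows through explicit seeds; simulation outputs are byte-stable for a given
seed. Text output writes floats at 12 significant digits so write→read→write
cycles are byte-identical.

## Known limitations

Covariate adjustment ("age, sex, inflammatory markers") cannot be
operationalized from summary statistics alone; supplying such GWAS as
additional MVMR exposure columns is the only supported mechanism. Weighted-
median/mode estimators, MR-PRESSO, Steiger filtering and multi-causal-variant
colocalization are out of scope. The mediation SE ignores correlation between
legs that share instruments. LD matrices must be provided; the package does not
compute LD from reference panels.
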