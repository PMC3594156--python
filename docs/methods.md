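# Methods

## The reciprocal two-disease design

The pipeline analyses two disease cohorts, each split into a primary and
a validation half, with each disease acting as the other's control. The
assumption that makes this work is that the two diseases share no risk
alleles: under it, any SNP whose allele frequency differs between the
cohorts is associated with exactly one of them, and the direction of the
difference relative to a normative population identifies which. The
design fails softly when the assumption is violated — a shared risk
allele shifts both cohorts together and goes undetected — which is a
property of the design itself, not of this implementation.

## Statistical machinery

**Trend test.** Association per SNP is the Cochran–Armitage trend test
with additive scores (0, 1, 2 minor-allele copies) on the 2×3 genotype
table, computed as T²/Var(T) with T = N·Σsᵢrᵢ − R·Σsᵢnᵢ and
Var(T) = R(N−R)/N · (N·Σsᵢ²nᵢ − (Σsᵢnᵢ)²). This equals N·r² for the
correlation r between score and case status, which the tests use as an
independent oracle. Degenerate tables (no genotype or status variation)
return statistic 0. The asymptotic χ²₁ p-value is anti-conservative for
very small tables; the permutation cross-check in the test suite runs at
n = 800 where the approximation is good.

**Genomic control.** Stratification inflates all trend statistics
approximately multiplicatively when structure is mild. λ is estimated as
the ratio of the 0.1-trimmed mean of the observed statistics to the
identically trimmed mean of the χ²₁ reference (computed by numerical
integration), which is robust to the handful of true associations in the
upper tail; with trim 0 it reduces to mean-based genomic control. λ is
floored at 1 when correcting (correction never sharpens a p-value), but
the raw estimate is reported so deflation is visible as a diagnostic.
The corrected p-value is the χ²₁ upper tail of statistic/λ. This scalar
correction is only valid for mild structure; the test suite exercises it
at λ ≈ 1.2–1.5, and the estimator's scale-equivariance is property-
tested. The same λ divides the Wald chi-square of the quantitative-trait
regressions.

**Quantitative traits.** Single-SNP ordinary least squares of trait on
minor-allele count; SNPs with no genotype variance among measured
samples are reported untestable rather than failing the scan. A logistic
model of disease on genotype plus gender backs the gender-confounding
check; perfect separation is flagged and the p-value reported missing.

**Odds ratios.** Allelic, reconstructed from group minor-allele
frequencies and allele counts (`round(maf × 2n)`), with Woolf log-OR 95%
intervals and the Haldane–Anscombe +0.5 correction (flagged) on zero
cells. Fisher's exact test is two-sided by the point-probability rule
(scipy's convention), checked exhaustively against a hypergeometric
enumeration oracle.

**Hardy–Weinberg.** The default screen is the 1-df goodness-of-fit
chi-square on expected counts from the observed allele frequency; the
conditional exact test (sum of heterozygote-count probabilities no
larger than the observed, given the allele count) is available via
`method="exact"`. Monomorphic SNPs return p = 1 and are flagged
uninformative — there is nothing to test and 0/0 expected counts are
avoided. The screen runs per cohort by default and flags a SNP if any
cohort fails, because pooled testing confounds genotyping artifacts with
genuine associations; pooled mode is available. HWE failures are review
flags, never automatic removals.

## Two-stage bookkeeping

Retention requires a joint (pooled-phase) p-value below the tier
threshold (5×10⁻⁷ significant, 1×10⁻⁵ suggestive) and replication in
both phases. The phase-level replication threshold is not fixed by the
design's published description, so it is configurable: 1×10⁻⁵ per phase
at the significant tier and nominal 0.05 per phase at the suggestive
tier by default — the latter reflecting that reported loci of this
design replicate at nominal levels. Clustering is single-linkage on
consecutive retained SNPs per chromosome with a closed ≤ 200 kb gap
bound and a ≥ 3-member minimum; the peak SNP minimises joint p with ties
to the smaller position; output is invariant to input row order. A
cluster is tier-significant when at least three members are
significant-tier SNPs. Classification uses allele-count (2n) Fisher
tables, consistent with the allelic odds-ratio convention; the normative
side is either a genotyped normal cohort or expected counts formed from
a frequency table at a declared reference size (default 100 diploids,
the clinic-normal cohort scale). Interval logic is 1-based closed
throughout; BED output converts to 0-based half-open and the conversion
is tested.

## Power simulation

The penetrance model is multiplicative on the odds scale: odds(Dd) =
OR·odds(dd), odds(DD) = OR²·odds(dd), with P(disease | dd) = 0.001. The
risk allele D is the **major** allele: the tabulated minor-allele
frequency is the frequency of the non-risk allele d, and dd — the rare
homozygote — carries the baseline risk. (Identifying D with the minor
allele instead produces a grid inconsistent with the reference powers by
up to a factor of several at low MAF; the major-allele orientation
reproduces every cell within Monte-Carlo error, so it is adopted as this
package's reading of the model.) Genotype frequencies are Hardy–Weinberg
at that allele frequency; case and control genotype distributions follow
by Bayes' rule. Sampling is retrospective — genotype counts drawn
multinomially given status, 400 per arm — which is equivalent to
prospective sampling under the model and avoids simulating ~400,000
unaffected individuals per replicate at baseline risk 0.001. The
rejection test is the uncorrected trend test (the simulation has no
stratification), 1000 replicates per cell by default (MC SE ≤ 0.016).
Under this model the implied case-control allelic odds ratio equals the
per-step OR to within 1% at baseline 0.001, which is property-tested.

## Synthetic cohorts

The generator draws each genotype binomially under HWE from a group
allele frequency: one shared baseline frequency per SNP (uniform on
[0.05, 0.5] by default), overridden at planted SNPs by a target-disease
frequency and an elsewhere frequency. There is no linkage-disequilibrium
model — the association tests are single-SNP, and cluster behaviour is
exercised by planting several adjacent SNPs sharing one frequency shift.
Stratification is Balding–Nichols: per-subpopulation frequencies drawn
Beta around the baseline with divergence F (default 0.02, mild
European-scale structure), and cohorts drawing samples from the
subpopulations in configurable proportions; planted SNPs are exempt so
their target frequencies stay exact. Missingness is injected uniformly
at random at a configurable rate (default 0 — the real missingness
mechanism of genotyping arrays is not modelled, only enough to exercise
the call-rate filter). Gender and sub-phenotype labels are drawn at the
study's cohort proportions (AMD ≈ 63.5% female, dry/UCNV/BCNV ≈
26/38/36%; POAG ≈ 56% female, NTG/HTG 20/80 with NTG the minority
subclass); age matching is by design and not simulated. The quantitative
trait is mean + effect × dosage + Gaussian noise (defaults 556 ± 35 µm,
the central-corneal-thickness scale), optionally measured on a random
subset of samples.

What passing tests on these cohorts does *not* show: robustness to LD
structure, to differential (non-random) missingness, to genotyping batch
effects, or to cryptic relatedness — none of which the generator
produces.

## Problem sizes and numerical choices

The test suite runs planted-locus recovery at 800 SNPs × 900 samples
(15 replicates) and null false-positive checks at 2000 SNPs × 900
samples (30 replicates); the stratification check uses 4000 SNPs. These
sizes put binomial/Monte-Carlo error bars comfortably inside the
asserted tolerances while keeping the full suite under a few minutes.
Power-grid comparisons use the standard error of the difference of two
independent 1000-replicate Monte-Carlo estimates, the correct error
model when the reference values are themselves simulation output.
Seeds are fixed everywhere; `numpy.random.default_rng` children are
spawned per cell/replicate so results are independent of evaluation
order. Minor-allele ties at 50/50 frequency break alphabetically;
heterozygote allele pairs are written in alphabetical order so a
read-write cycle is byte-stable.

## Known limitations

* Genomic control is a scalar correction; strong or non-exchangeable
  structure (λ well above ~2) is not corrected adequately and should be
  handled upstream.
* The exact estimator behind the published "0.1-trimmed variance"
  stratification correction is not restated in the design's description;
  the trimmed-mean genomic control implemented here is this package's
  declared interpretation.
* Joint-phase evidence is the pooled-count test, not a meta-analytic
  combination of phase statistics.
* No X-chromosome dosage model, no imputation, no LD-aware clumping.
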