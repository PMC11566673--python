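# Methods

## Statistics

**Empirical accuracy.**  For a variant with truth genotypes
*gᵢ* ∈ {0, 1, 2} (alternate-allele counts) and imputed values *xᵢ*
(best-guess GT in {0, 1, 2}, or dosage DS in [0, 2]) across the target
samples, the empirical accuracy is the Pearson correlation
*r* = cov(g, x) / (σ_g σ_x) and Rsq_emp = *r*².  Missing cells on either
side drop the (variant, sample) pair from all statistics of that variant
(pairwise deletion; denominators are reported as `n_pairs`).  *r* is
non-estimable — reported as `NA` with a reason code, never 0-filled —
when fewer than two complete pairs remain or when a vector is constant:
in GT mode the variant must segregate in both truth and imputed calls, in
DS mode the truth must segregate and the dosages must not be constant.

**Allele-level error rates.**  With per-sample signed differences
*xᵢ − gᵢ*:

    fp_alleles = Σ max(xᵢ − gᵢ, 0)      fn_alleles = Σ max(gᵢ − xᵢ, 0)
    FPR = 100 · fp / Σ(2 − gᵢ)          FNR = 100 · fn / Σ gᵢ
    AER = 100 · (fp + fn) / (2 n)

This is the unique allele-level decomposition in which FP + FN counts sum
to the total number of wrongly imputed alleles and the denominators are
the total reference and alternate allele counts; the conservation
identity `fp + fn = AER/100 · 2n` holds exactly for every variant and is
asserted in the test suite.  A zero denominator (no reference or no
alternate alleles in truth) makes the corresponding rate undefined.
"Average percentage" is always per variant across samples, matching the
per-variant framing of the correlation; aggregation across variants
weights variants equally.

**Software quality scores.**  All three scores are computed from
genotype posteriors (p₀, p₁, p₂) via the per-sample expected dosage
dᵢ = p₁ + 2p₂, expected squared dosage eᵢ = p₁ + 4p₂, and estimated
frequency p̂ = Σdᵢ / 2N:

* Beagle-style `DR2 = (Σdᵢ² − (Σdᵢ)²/N) / (Σeᵢ − (Σdᵢ)²/N)` — dosage
  variance over the posterior-implied variance of the true genotypes.
* MACH/Minimac-style `Rsq = mean_h (D_h − p̂)² / (p̂(1 − p̂))` on haploid
  dosages.  The diploid fallback is the classical form
  `Var(d) / (2 p̂ (1 − p̂))`, which equals the haploid statistic in
  expectation for independently paired haplotypes.  (Contributing each
  half-dosage twice instead would halve the statistic — Var(d/2) =
  Var(d)/4 against p̂(1−p̂) — and break the agreement with empirical
  Rsq that all these scores are meant to deliver.)
* IMPUTE-style `INFO = 1 − Σ(eᵢ − dᵢ²) / (2N p̂ (1 − p̂))` — observed
  over complete information about the allele frequency.

Zero-denominator conventions: DR2 → 0; INFO → 1 if all posteriors are
degenerate (complete information about a monomorphic site) else 0;
MACH → 0.  Denominators at or below 1e-12 count as zero.  Scores are
capped into [0, 1]; raw MACH values are also returned uncapped.  DR2 and
INFO estimate the same ratio on calibrated posteriors; at finite N their
denominators (posterior-implied vs HWE variance at p̂) differ by an
O(1/√N) sampling term, so per-variant differences of a few hundredths
are expected at N = 500 even though the two agree in level (mean
absolute difference well under 0.02).

## Calibration and equivalent thresholds

Variants are binned by Rsq_soft into width-0.05 bins over [0, 1]
(half-open [k·w, (k+1)·w), score 1 in the last bin; width configurable).
Each bin records n, mean, median, quartiles and 1.5·IQR whisker bounds of
its Rsq_emp distribution.  The *equivalent threshold* for a target mean
accuracy (default 0.8) is the smallest bin lower edge such that every
eligible bin (n ≥ 50 by default — sparser bin means are too noisy to
anchor a filtering rule) at or above it has mean Rsq_emp ≥ target,
scanning from the top of the score range.  A "cumulative" alternative
(smallest edge t such that the pooled mean over all variants with score
≥ t meets the target) is reported alongside; pooling dilutes the target
with the high-score mass, so it is always at or below the bin-wise
threshold.  "Pass" is score ≥ threshold and "achieve" is Rsq_emp ≥
target, both inclusive.

Filtering is audited as: TP = pass ∧ achieve, FP = pass ∧ ¬achieve (% of
passing), FN = ¬pass ∧ achieve (% of non-passing), overall and per
SNP/INDEL × MAF group (common: MAF > 0.05; the boundary value 0.05
falls in the less-common group).

## Reference filters

Observed heterozygosity — the fraction of non-missing calls that are
heterozygous — is used for the excess-het filter because the artefacts it
targets (collapsed segmental duplications misaligning short reads)
manifest directly in the calls.  Windows of 0.5 Mb tile each chromosome
from position 0; a window with ≥ 2% of its variants above het 0.55
(strict) has exactly those variants removed.  The default step equals the
window, which makes the filter idempotent; a smaller step gives true
sliding windows with removal as the union over flagged windows.  The MAC
filter retains variants with minor allele count ≥ 4 (inclusive), counted
over non-missing calls.  The cascade order is biallelic (at read time) →
MAC → het-excess; window percentages are computed on MAC-passing
variants.

## Region classification

Every variant receives exactly one class.  Chromosomes named in
`x_chroms` split at the PAR boundary: positions ≤ boundary are non-PAR,
above it PAR (the PAR sits at the distal end of the X; the source
coordinate does not state which side owns the boundary base, so this
convention is fixed and configurable).  The real-data default is
133,300,518 bp; the simulator uses 4 Mb in its own coordinate system.
Variant matching between call sets is exact on (chrom, pos, ref, alt)
after uppercasing — no indel left-normalization is attempted, so inputs
must share a reference representation; same-position/different-allele
pairs are counted separately in the match report.

## The synthetic-data generator

The generator emulates the data a sequence-imputation evaluation
consumes, not the imputation HMMs themselves: the pipeline only sees
(GT, DS, GP, Rsq_soft) and is agnostic to how posteriors arose.

*Truth.*  Per variant, a minor allele frequency is drawn from a spectrum
(default: density ∝ 1/p truncated to the panel's resolution, the
neutral site-frequency shape; folded Beta(a, b) available), a reference
panel of 400 haplotypes is sampled at that frequency and conditioned on
polymorphism (MAC ≥ 1 both sides), and 70 diploid target samples are
formed by pairing panel haplotypes.  ~7% of variants are INDELs.
Variants are placed uniformly within declared chromosome spans: chr1
0–8 Mb autosome baseline, 8–10 Mb error hotspot (multiplier up to 6),
10–10.5 Mb het-excess span, chrX 0–4 Mb non-PAR and 4–5 Mb PAR
(multiplier up to 4).  Within elevated spans, per-variant multipliers are
drawn uniformly between 1 and the span maximum — per-site error in
duplicated or poorly aligned regions is heterogeneous, and this is what
lets a score filter *improve* a poor region rather than empty it.

*Imputation error.*  Per (variant, sample) cell, a latent observation
y equals the truth with probability 1 − λ_v and is otherwise drawn from
the HWE genotype distribution at the panel frequency.  The emitted
posterior is the exact Bayes posterior of that observation model,

    gp = (1 − λ_v)·onehot(y) + λ_v·HWE(p),

so the posteriors are *calibrated*: conditional on gp, the truth is
distributed as gp.  Centering the mixture on the observation rather than
on the truth itself is what makes calibration exact — a truth-centred
mixture would make argmax(gp) always equal the truth and the scores
systematically pessimistic.  The error intensity
λ_v = λ·(0.5/max(maf, 0.01))^0.25·m_v (base λ = 0.04) rises at low MAF
and in high-error spans; intensities outside [0, 1] raise an error
rather than clip.  GT is argmax(gp) with ties to the lower genotype;
DS = p₁ + 2p₂.  A pure allele-flip model (each truth allele flips
independently at rate λ_v; degenerate posteriors) is available for exact
allele-level error-rate checks.  Scores come from the configured
estimator applied to the simulated posteriors (DR2 by default), then
transformed s → s^γ: γ > 1 deflates (Minimac-like), γ < 1 inflates
(Beagle/IMPUTE-like); `score_model="oracle"` copies the realised
empirical Rsq instead.  The truth stream uses the seed directly; the
imputation stream uses seed + 1, so one truth set can be re-imputed
under different error settings.

*What the generator does not model:* linkage disequilibrium beyond
shared haplotype pairs, coalescent genealogy, recombination maps,
pedigree structure, male hemizygosity on X (all samples diploid), and
genotyping error in the truth itself.  Passing tests therefore
demonstrate that the statistics, filters and calibration machinery are
correct and recover designed effects — not that any particular real
data set will show those effects at the same magnitude.

## Problem sizes and numerical choices

The bundled checks run, per fixed seed: hand-worked examples (exact, to
stated precision); Pearson cross-checks against an explicit-sum oracle at
1e-12 on 1,000 random vectors; allele-conservation on a 10,000-variant
simulation (1e-9); the perfect-imputation limit on 5,000 × 70; allele-flip
recovery of ε = 0.05 within 3 binomial SE on 2,000 × 70; calibration
recovery on 100,000 variants at N = 500 in 20,000-variant chunks with the
MAC ≥ 4 reference filter applied (bin agreement ≤ 0.05 for bins with
n ≥ 500 — the bin-wise property is asymptotic in N; at N = 70 the
sampling noise of score and accuracy induces visible regression-to-the-
mean inside bins); γ-ordering of thresholds on 8,000 × 70; and the
regional/MAF filtering effects on 30,000 × 70.  `scripts/acceptance.py`
uses a 60,000-variant calibration stream, which is past the point where
the reported bin gaps stabilise.

Floats are written to 6 decimal places in all tables (round-trip
tolerance 5e-7); undefined values are `NA`.  Percentages follow the
denominators named in their column headers.  Equality comparisons on
score-bin edges use half-open intervals with the top bin closed.
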