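# imputeqc

Empirical accuracy evaluation and quality-score calibration for genotype
imputation.

Genotype imputation infers untyped variants from a reference panel of
haplotypes, and every major imputation tool reports a per-variant quality
score — Beagle's `DR2`, Minimac's `R2`, IMPUTE's `INFO` (collectively
*Rsq_soft*) — intended to estimate the squared correlation between imputed
and true genotypes.  But the three scores sit on different effective
scales: the same numeric cutoff removes very different sets of variants
depending on the tool.  Anyone merging imputed data across studies (e.g.
for a meta-GWAS) therefore needs *software-equivalent thresholds*: the
per-tool score cutoff at which retained variants achieve a common
empirical accuracy floor.

`imputeqc` provides the full workflow against a truth set:

* **Per-variant empirical accuracy.**  For truth genotypes *g* ∈ {0, 1, 2}
  and imputed genotypes (best-guess GT, or dosage DS ∈ [0, 2]), the
  empirical accuracy *r* is the Pearson correlation across samples and
  *Rsq_emp* = *r*².  GT-mode *r* is estimable only when the variant
  segregates in both truth and imputed calls.  Allele-level errors are
  decomposed into FPR (% of reference alleles imputed as alternate), FNR
  (% of alternate alleles imputed as reference) and AER (% of all alleles
  wrongly imputed), with FP + FN allele counts summing exactly to the
  total allele errors.  Concordance, segregation error rates, 1 Mb window
  summaries and MAF-binned summaries round out the statistics.
* **The three software scores, re-implemented** from genotype posteriors:
  DR2 = Var(d) / posterior-implied Var(g); MACH-Rsq =
  Var(dosage) / p̂(1−p̂) (haploid) or Var(d)/(2p̂(1−p̂)) (diploid);
  INFO = 1 − Σ(eᵢ−dᵢ²) / (2N p̂(1−p̂)), where dᵢ = p₁+2p₂ and
  eᵢ = p₁+4p₂ per sample.
* **Reference-panel filters**: minor allele count (MAC ≥ 4 by default)
  and the excess-heterozygosity window filter (0.5 Mb windows; where ≥ 2%
  of variants have observed het > 0.55, all such variants are removed —
  the signature of collapsed segmental duplications).
* **Score calibration**: bin variants by Rsq_soft, summarise the Rsq_emp
  distribution per bin (Fig-3-style boxplot statistics), read off the
  equivalent threshold for a target mean Rsq_emp, and audit the filter
  with TP/FP/FN accounting overall and per SNP/INDEL × common/less-common
  MAF group.
* **A synthetic-data generator** that emulates the study design this kind
  of evaluation runs on: a skewed MAF spectrum, ~7% INDELs, 70 diploid
  target samples, region-structured error (autosome baseline, a PAR-like
  high-error region on X, a localized error hotspot, a het-excess span)
  and calibrated genotype posteriors whose scores can be deliberately
  miscalibrated (`s → s^γ`) in either the Minimac-like (deflated) or
  Beagle/IMPUTE-like (inflated) direction.

X-chromosome variants are classified non-PAR/PAR at a configurable
boundary (default 133,300,518 bp, the bovine ARS-UCD1.2 coordinate;
positions at or below the boundary are non-PAR).

## Worked example

Simulate a truth/imputed pair, evaluate it, and calibrate the score:

```bash
imputeqc simulate --seed 7 --n-variants 5000 -o sim
imputeqc evaluate -t sim/truth.vcf -i sim/imputed.vcf --par-boundary 4000000 -o eval
imputeqc calibrate -s eval/stats_imputed.tsv --target 0.8 -o cal
```

which prints

```
simulated 5000 variants x 70 samples -> sim (seed 7)
wrote statistics for 1 call set(s) to eval (manifest 20953a7635a0)
stats_imputed: equivalent threshold 0.700 (target 0.8)
```

`eval/stats_imputed.tsv` holds one row per matched variant:

```
chrom   pos vclass   region  maf_ref  rsq_soft     r_ds      aer  concordance
    1  5254    SNP AUTOSOME   0.1250  0.890245 0.967539 0.714286    98.571429
    1 18009    SNP AUTOSOME   0.0350  0.000000      NaN 0.714286    98.571429
    1 25680    SNP AUTOSOME   0.4525  0.912426 1.000000 0.000000   100.000000
    1 26210  INDEL AUTOSOME   0.1975  0.912369 0.931161 1.428571    98.571429
```

The second variant shows a non-estimable `r_ds` (`NA` on disk): its
dosages carry no variance, so correlation is undefined rather than
silently zero.  The calibrate step reports the equivalent threshold
(0.70 here: the lowest 0.05-wide score bin from which every
well-populated bin upward averages Rsq_emp ≥ 0.8) and the confusion
audit of filtering at that threshold:

```
          group  n_pass  pct_pass  pct_tp_of_pass  pct_fp_of_pass  pct_fn_of_notpass
            ALL    3632 87.496989       77.340308       22.659692          20.809249
     SNP/common    1843 90.210475       82.365708       17.634292          16.000000
SNP/less_common    1550 84.284937       71.096774       28.903226          24.567474
```

False positives are variants passing the score threshold whose empirical
accuracy misses the target (as % of passing variants); false negatives
failed the score but achieved the target (as % of non-passing variants).
Rare variants show more of both — their per-variant score and accuracy
estimates are noisier at 70 samples.

The same functions are importable directly
(`imputeqc.compute_stats`, `imputeqc.build_curve`,
`imputeqc.equivalent_threshold`, ...), operating on pandas DataFrames.

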