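# Methods

## Study design being modelled

A prospective serial-monitoring design in metastatic colorectal cancer:
plasma is drawn pretreatment (`C0`) and immediately before treatment
cycles 2–4 (`C1`–`C3`, two-week cycles), each sample deep-sequenced
(>10,000×) on a ~50-gene amplicon panel alongside matched
peripheral-blood leukocytes (PBL). Radiologic response (RECIST) is
assessed once, after cycle 4; progressive disease (PD) is the positive
class throughout. The analytic chain is: somatic filtering → candidate
mutation (maximal pretreatment VAF) → log2 fold changes vs `C0` →
ROC/Youden cutoff per marker and interval → PFS stratification by the
ctDNA C1/C0 cutoff → tissue–plasma RAS concordance.

## Filtering model

Raw caller output is reduced to somatic calls in four ordered steps;
order is observable in the audit log and each step is idempotent.

1. **Primary thresholds** (all strict, matching the published
   inequalities): sample average depth > 10,000×; variant coverage
   (alt reads) > 10; VAF > 0.5%; error-model *p* < 0.01. The caller's
   proprietary *p*-value is replaced by a transparent stand-in: the
   one-sided exact binomial tail P(X ≥ alt | n = depth, p = e) against
   a fixed per-base error rate e (default 1×10⁻³, typical of
   amplicon/semiconductor chemistries after QC). One-sided is the
   natural choice for an error model — only an excess of alt reads is
   evidence of a variant.
2. **Strand bias**: a two-sided Fisher exact test on
   [[alt_fwd, alt_rev], [ref_fwd, ref_rev]] replaces manual pileup
   inspection. A call is dropped only when p < 10⁻³ **and** the minor
   strand carries < 10% of alt reads; the guard protects genuine
   low-coverage variants with mild imbalance. Deterministic and
   auditable where visual review is neither.
3. **Hotspot whitelist**: calls are matched at allele level
   (chrom, pos, ref, alt), not position level — a panel's hotspot
   manifest enumerates specific substitutions, and allele-level
   matching is the stricter, safer reading. Multiallelic records are
   split on read; no further normalization is attempted.
4. **Germline subtraction**: a plasma call is germline iff the matched
   PBL sample carries the identical allele at VAF ≥ 1%. The threshold
   is deliberately low (heterozygous germline sits near 50%): cheap
   insurance against losing a true somatic call to PBL sequencing
   noise is unnecessary, while missing germline is costly.

Read-length QC keeps reads of 60–160 bp (inclusive); an empty input
reports the 0/0 case as NaN rather than inventing a fraction.

## Detection limit

The LOD is the smallest nominal mutant fraction whose replicate
measurements completely separate from the negative controls —
strictly: min(positives) > max(negatives), ties failing, equivalent to
a zero-false-positive operating point. No probit or limit-of-blank
model is fitted. With the default standards design (0/0.5/1% nominal,
10 replicates, 10,000×, e = 10⁻³) background measures ~0.1% VAF and the
0.5% level separates, giving LOD = 0.5%; this LOD feeds the 0.5%
primary VAF threshold and the fold-change floor (LOD/2).

## Monitoring

The candidate is the maximal-VAF filtered `C0` call; ties break toward
higher alt-read support, then the lexicographically smallest allele
key, making selection order-invariant. Patients with no filtered `C0`
calls are excluded ("no detectable ctDNA"), mirroring the study
workflow.

Fold changes are log2(max(x_t, floor) / max(x_0, floor)) — a standard
left-censoring substitution keeping log2 finite when a marker clears.
Floors: ctDNA 0.25% VAF (half the LOD); CEA 0.5 ng/mL and CA19-9
0.6 U/mL (assay lower quantitation limits). Both baseline-referenced
(Ct/C0, the default used in all analyses) and adjacent-cycle (Ct/Ct−1)
ratios are implemented.

If the candidate falls below the 0.5% filter gate at a later timepoint
but ≥ 3 raw alt reads remain, the raw VAF is used (flagged
`raw_fallback` in outputs) — otherwise the filter would zero genuine
residual signal and exaggerate declines. Whether requantification used
raw or filtered data is an open question of the design; the fallback is
this package's choice and is always logged.

Classification is strict: fold change > cutoff predicts PD; a value
exactly at the cutoff is non-PD.

## Diagnostics

- Mann–Whitney U: exact enumeration when the pooled sample is ≤ 20 and
  tie-free, otherwise the tie-corrected normal approximation; an
  all-tied sample returns p = 1.
- AUC is the empirical (concordant + half-tied pairs) estimator; its
  Z test against 0.5 uses the DeLong placement-variance estimator. A
  degenerate variance (perfect separation at tiny n) is flagged
  `small_sample` rather than silently reporting an untrustworthy p.
- Youden cutoff: J is evaluated at thresholds midway between adjacent
  distinct scores plus ±∞; midpoints give a classifier that is stable
  to perturbation of either neighboring score (an `observed` style is
  available). Ties on J break toward higher sensitivity, then lower
  cutoff. An uninformative marker (best J ≤ 0) returns −∞ with a
  `degenerate` flag.
- Correlated ROC curves are compared with DeLong's placement
  covariance; a zero-variance difference (identical rankings) returns
  p = 1.
- All proportion metrics carry exact Clopper–Pearson intervals
  (beta-quantile form). This method exactly reproduces the k = n
  interval bounds a table of this kind prints (e.g. 54.1 for 6/6,
  88.1 for 29/29), which is how the CI method was identified. Metrics
  with zero denominators are flagged undefined instead of failing the
  row. Percentages are reported to one decimal, AUC to three; p-values
  below 0.001 print as "<0.001". No multiple-testing correction is
  applied across the nine marker/interval combinations (none was in
  the design being reproduced); the report notes this.

## Survival

PFS runs from cycle 1 to first progression or death; otherwise
censored. Kaplan–Meier estimation and the two-group log-rank test are
delegated to lifelines; the median is the earliest time the curve
reaches 0.5 (infinite when never reached), events precede censorings at
tied times, and no median CI is reported. Stratification assigns
patients by the strict cutoff rule; if everyone falls on one side the
comparison aborts with an explicit message.

## Synthetic cohort generator

Defaults encode the study conditions: 41 patients, PD fraction 6/41,
four timepoints, candidate `C0` VAF lognormal with median 7.95%
(log-sd 1.0, truncated to (0, 0.8]), per-cycle additive log2
fold-change shifts N(−1.5, 0.6) for non-PD and N(+0.5, 0.6) for PD
(direction is all the design states; these magnitudes place a separating
cutoff near zero at the observed accuracy), 10% per-timepoint monotone
dropout, sequencing depth 12,000× (the primary filter requires average
depth strictly above 10,000, so "minimum 10,000×" is modelled from
above), per-base error 10⁻³, and exact-count gene prevalences
(TP53 29/41, KRAS 22/41, APC 20/41, …). Serum markers are lognormal
with the group separation lagged one cycle — CEA/CA19-9 discriminate
only from C2–C3, as conventional markers do. PFS is exponential with
medians 2 (PD) and 9 (non-PD) months, administratively censored at 24.
Tissue RAS pairing reproduces the paired-cohort structure: 25 pairs,
15 tissue-mutant of which 14 are fully detected in plasma, 10
concordant wild-type. Contaminants are injected with ground-truth tags:
germline polymorphisms (VAF ≈ 50%, mirrored in PBL, at reserved
whitelist sites), strand artifacts (≥ 95% of alt reads on one strand),
and sub-threshold off-panel noise (VAF < 0.3%).

Seeding: one root seed; per-patient streams derive from
`SeedSequence(seed, spawn_key=(stream, patient_index))`, so enlarging a
cohort does not reshuffle existing patients. Identical configurations
reproduce byte-identical outputs.

For cutoff-recovery experiments the generator accepts truncation
bounds on the per-cycle shifts (`log2fc_bounds`, used as non-PD < −0.4
and PD > +0.1 in the validation studies), which guarantees a known
separating threshold between the groups; default generation is
untruncated.

**What the generator does not emulate:** read-level sequencing (no
FASTQ/instrument simulation — counts are binomial at the stated depth),
clonal heterogeneity and divergent per-mutation kinetics (all of a
patient's mutations share one tumor-burden trajectory), CHIP-like
PBL-restricted clones, inter-site error-rate variation, non-exponential
PFS hazards, and informative dropout (missingness is independent of
response). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real cfDNA data.

## Validation experiments and their scale

The repeated-run studies (in `ctdnaflow.experiments`) use 50 seeded
n=41 cohorts for cutoff/KM recovery and 500 replicates of n=20+20 for
log-rank type-I error — sizes chosen so the full suite and the
reproduction script each complete in about a minute and a half on one
CPU while leaving Monte-Carlo noise well below the margins being
asserted.

## Known limitations

- The Kaplan–Meier median of the above-cutoff group rests on only ~6–8
  subjects; the sampling distribution of a median from so few
  exponential observations is wide (the central order statistic of 6
  draws with median 2 falls outside [1, 4] months roughly a quarter of
  the time), so per-run median recovery into tight bands cannot be
  highly reliable at this n. The recovery studies report the observed
  rates rather than hiding this.
- Apparent (resubstitution) performance only: cutoffs are evaluated on
  the data that chose them, as in the original design — no
  cross-validation.
- The trajectory-distribution defaults are calibrated to reproduce the
  design's headline behaviour, not extracted from per-patient data
  (none are published).
- Germline subtraction assumes the PBL sample is sequenced comparably
  deeply; a shallow PBL sample would let germline leak through.
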