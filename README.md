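# ctdnaflow

Serial monitoring of circulating tumor DNA (ctDNA) to predict treatment
response in metastatic colorectal cancer, as a tested, reproducible
pipeline.

In serial liquid-biopsy monitoring, plasma is drawn before each early
treatment cycle (pretreatment `C0`, then `C1`–`C3` before cycles 2–4)
and sequenced on a deep (>10,000×) cancer-gene amplicon panel. The
variant with the maximal allele fraction in the pretreatment plasma is
each patient's **candidate mutation**, and its trajectory — summarized
as log2 fold changes, e.g. ctDNA log2(C1/C0) — is an early readout of
tumor burden, weeks before the first CT evaluation. `ctdnaflow`
implements the full analysis for oncology/bioinformatics researchers
working with this study design:

- **Somatic filtering** of raw deep-panel calls in four steps: strict
  thresholds (average depth > 10,000×, variant coverage > 10, VAF >
  0.5%, error-model *p* < 0.01, with a one-sided exact binomial test
  against a fixed per-base error rate as the *p*-value), a Fisher
  exact strand-bias screen with a minor-strand-fraction guard, a
  2,855-style hotspot whitelist restriction, and germline subtraction
  against matched peripheral-blood leukocytes (PBL). Every dropped call
  is audit-logged with its step and reason.
- **Detection-limit calibration** from replicate reference standards:
  the LOD is the smallest nominal mutant fraction whose replicates
  completely separate from negative controls (min positive > max
  negative).
- **Monitoring**: candidate selection, left-censored log2 fold changes
  for ctDNA and the serum markers CEA and CA19-9, and cutoff
  classification (fold change > cutoff predicts progressive disease).
- **Diagnostics**: Mann–Whitney group comparison, empirical ROC AUC
  with a DeLong-variance Z test, the Youden-index optimal cutoff
  (J = sensitivity + specificity − 1), DeLong comparison of correlated
  ROC curves, and sensitivity/specificity/PPV/NPV/accuracy with exact
  Clopper–Pearson 95% intervals.
- **Survival**: Kaplan–Meier progression-free survival stratified by
  the cutoff, compared by log-rank test.
- **Concordance**: tissue–plasma RAS agreement at the amino-acid
  substitution level with tissue as reference.
- **Synthetic cohorts**: a generator that emulates the study design
  (n≈41, ~15% progressors, lognormal pretreatment VAFs around 8%,
  group-specific per-cycle fold-change distributions, monotone
  missingness, injected germline/strand-artifact/noise contaminants,
  and 0/0.5/1% reference standards) so the whole pipeline is testable
  without patient data.

## Worked example

```python
from ctdnaflow import CohortConfig, generate_full_cohort, run_pipeline

cohort, whitelist = generate_full_cohort(CohortConfig(seed=7))
result = run_pipeline(cohort, whitelist)

row = next(r for r in result.rows if r.marker == "ctDNA" and r.interval == "C1/C0")
acc = row.metrics["accuracy"]
print(f"ctDNA log2(C1/C0): n={row.n}, AUC={row.roc.auc:.3f}, "
      f"cutoff={row.roc.cutoff:.3f}, accuracy={acc.estimate:.1f}% "
      f"({acc.ci_low:.1f}-{acc.ci_high:.1f})")
surv = result.survival
print(f"PFS above vs below cutoff: median {surv.above.median:.1f} vs "
      f"{surv.below.median:.1f} months (log-rank p={surv.logrank.p:.4f})")
```

prints

```
ctDNA log2(C1/C0): n=36, AUC=0.983, cutoff=-0.174, accuracy=97.2% (85.5-99.9)
PFS above vs below cutoff: median 2.4 vs 9.6 months (log-rank p=0.0037)
```

Of the 41 simulated patients, 36 have a cycle-1 draw; the fold change
of the candidate mutation separates progressors from non-progressors
almost perfectly (AUC 0.983), the Youden cutoff sits just below zero
(ctDNA that fails to fall predicts progression), and patients above the
cutoff progress about four times sooner.

The same analysis is available from the shell:

```bash
ctdnaflow simulate --out cohort/ --seed 7
ctdnaflow lod --standards cohort/standards.tsv
ctdnaflow run-all --cohort cohort/ --out reports/
```

`reports/` then contains the nine-row performance table
(`table1.tsv` + `report.json`), per-call filter audit log, fold
changes, survival table and a Kaplan–Meier SVG.

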