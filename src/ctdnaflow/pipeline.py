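"""End-to-end analysis: filter -> candidate -> fold changes -> diagnostics
-> survival -> concordance, with a Table-style TSV report and a
machine-readable JSON twin.

The nine diagnostic rows are the three markers (ctDNA, CEA, CA19-9)
crossed with the three baseline-referenced intervals (C1/C0, C2/C0,
C3/C0). Each row reports the Mann–Whitney p for the PD vs non-PD
comparison, the AUC with its Z-test p, the Youden-optimal cutoff, and
sensitivity/specificity/PPV/NPV/accuracy (with exact 95% CIs) of the
``fold change > cutoff`` rule. Survival is stratified by the ctDNA
C1/C0 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from . import fileio
from .cohort import PatientRecord, detection_rate, gene_mutation_frequencies
from .concordance import ConcordanceResult, ras_concordance
from .diagnostics import (
    ConfusionMatrix,
    MetricWithCI,
    RocResult,
    confusion_metrics,
    delong_compare,
    mann_whitney,
    youden_cutoff,
)
from .filters import FilterThresholds, filter_pipeline
from .monitoring import (
    MARKER_CTDNA,
    MARKERS,
    PD,
    FloorLevels,
    NoDetectableCtDNA,
    classify,
    select_candidate,
    track_patient,
)
from .survival import (
    DegenerateStratification,
    KMEstimate,
    LogrankResult,
    SurvivalRecord,
    km_estimate,
    logrank_test,
    stratify_by_cutoff,
)

logger = logging.getLogger("ctdnaflow")

INTERVALS = ("C1", "C2", "C3")


@dataclass
class DiagnosticRow:
    marker: str
    interval: str  # e.g. "C1/C0"
    n: int
    n_pd: int
    n_nonpd: int
    mw_p: float
    roc: RocResult
    matrix: ConfusionMatrix
    metrics: dict[str, MetricWithCI]


@dataclass
class SurvivalComparison:
    cutoff: float
    above: KMEstimate
    below: KMEstimate
    logrank: LogrankResult


@dataclass
class PipelineResult:
    cohort: list[PatientRecord]
    candidates: dict[str, object]
    excluded: list[str]
    fold_changes: list
    rows: list[DiagnosticRow] = field(default_factory=list)
    skipped_rows: list[dict] = field(default_factory=list)
    delong: list[dict] = field(default_factory=list)
    survival: SurvivalComparison | None = None
    survival_skipped: str | None = None
    concordance: ConcordanceResult | None = None
    audit_rows: list[dict] = field(default_factory=list)
    summaries: dict = field(default_factory=dict)


def _fc_lookup(fold_changes, marker: str, to_tp: str) -> dict[str, float]:
    return {
        fc.patient_id: fc.value
        for fc in fold_changes
        if fc.marker == marker and fc.to_timepoint == to_tp and fc.from_timepoint == "C0"
    }


def run_pipeline(
    cohort: list[PatientRecord],
    whitelist,
    thresholds: FilterThresholds | None = None,
    floors: FloorLevels | None = None,
    outdir: str | Path | None = None,
    alpha: float = 0.05,
    cutoff_style: str = "midpoint",
) -> PipelineResult:
    """Run the full analysis over a cohort with raw calls attached."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    thresholds = thresholds or FilterThresholds()
    floors = floors or FloorLevels()

    # stage 1: four-step filtering of every plasma sample
    logger.info("stage filter: %d patients", len(cohort))
    audit_rows: list[dict] = []
    for patient in cohort:
        for tp, sample in sorted(patient.samples.items()):
            res = filter_pipeline(
                sample.raw_calls, patient.pbl_calls, sample.avg_depth, whitelist, thresholds
            )
            sample.filtered_calls = res.passed
            for entry in res.audit:
                audit_rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "timepoint": tp,
                        "chrom": entry.call.chrom,
                        "pos": entry.call.pos,
                        "ref": entry.call.ref,
                        "alt": entry.call.alt,
                        "vaf": entry.call.vaf,
                        "step": entry.step,
                        "reason": entry.reason,
                        "truth_class": entry.call.truth_class or "",
                    }
                )

    # stage 2: candidate selection (maximal-VAF pretreatment mutation)
    logger.info("stage candidates")
    candidates, excluded = {}, []
    for patient in cohort:
        c0 = patient.samples.get("C0")
        try:
            if c0 is None:
                raise NoDetectableCtDNA(f"patient {patient.patient_id}: no C0 sample")
            candidates[patient.patient_id] = select_candidate(
                c0.filtered_calls or [], patient.patient_id
            )
        except NoDetectableCtDNA:
            excluded.append(patient.patient_id)

    # stage 3: fold changes
    logger.info("stage fold changes")
    fold_changes = []
    for patient in cohort:
        cand = candidates.get(patient.patient_id)
        if cand is None:
            continue
        fold_changes.extend(track_patient(patient, cand, floors))

    result = PipelineResult(
        cohort=cohort,
        candidates=candidates,
        excluded=excluded,
        fold_changes=fold_changes,
        audit_rows=audit_rows,
    )

    # stage 4: diagnostics (3 markers x 3 intervals)
    logger.info("stage diagnostics")
    is_pd = {p.patient_id: p.is_pd for p in cohort}
    for marker in MARKERS:
        for to_tp in INTERVALS:
            values = _fc_lookup(fold_changes, marker, to_tp)
            scores = list(values.values())
            labels = [is_pd[pid] for pid in values]
            interval = f"{to_tp}/C0"
            if sum(labels) == 0 or sum(labels) == len(labels):
                result.skipped_rows.append(
                    {
                        "marker": marker,
                        "interval": interval,
                        "reason": "both response groups required; "
                        f"PD={sum(labels)}, non-PD={len(labels) - sum(labels)}",
                    }
                )
                logger.warning("diagnostics skipped for %s %s", marker, interval)
                continue
            roc = youden_cutoff(scores, labels, cutoff_style=cutoff_style)
            mw = mann_whitney(
                [s for s, l in zip(scores, labels) if l],
                [s for s, l in zip(scores, labels) if not l],
            )
            predicted = [classify(s, roc.cutoff) == PD for s in scores]
            matrix = ConfusionMatrix.from_predictions(predicted, labels)
            result.rows.append(
                DiagnosticRow(
                    marker=marker,
                    interval=interval,
                    n=len(scores),
                    n_pd=sum(labels),
                    n_nonpd=len(labels) - sum(labels),
                    mw_p=mw.p,
                    roc=roc,
                    matrix=matrix,
                    metrics=confusion_metrics(matrix, alpha),
                )
            )

    # pairwise DeLong comparison of the ctDNA ROC curves (common patients)
    ctdna_rows = {r.interval: r for r in result.rows if r.marker == MARKER_CTDNA}
    for (tp_a, tp_b) in combinations(INTERVALS, 2):
        ia, ib = f"{tp_a}/C0", f"{tp_b}/C0"
        if ia not in ctdna_rows or ib not in ctdna_rows:
            continue
        va = _fc_lookup(fold_changes, MARKER_CTDNA, tp_a)
        vb = _fc_lookup(fold_changes, MARKER_CTDNA, tp_b)
        common = sorted(set(va) & set(vb))
        labels = [is_pd[pid] for pid in common]
        if len(common) < 3 or sum(labels) in (0, len(labels)):
            continue
        cmp_res = delong_compare(
            [va[p] for p in common], [vb[p] for p in common], labels
        )
        result.delong.append(
            {
                "marker": MARKER_CTDNA,
                "intervals": f"{ia} vs {ib}",
                "n": len(common),
                "auc_1": cmp_res.auc_1,
                "auc_2": cmp_res.auc_2,
                "p": cmp_res.p,
            }
        )

    # stage 5: survival stratified by the ctDNA C1/C0 cutoff
    logger.info("stage survival")
    c1_row = ctdna_rows.get("C1/C0")
    if c1_row is None:
        result.survival_skipped = "no ctDNA C1/C0 diagnostic row available"
    else:
        records = {
            p.patient_id: SurvivalRecord(
                patient_id=p.patient_id, time=p.pfs_months, event=p.pfs_event
            )
            for p in cohort
        }
        fcs = [
            fc
            for fc in fold_changes
            if fc.marker == MARKER_CTDNA
            and fc.to_timepoint == "C1"
            and fc.from_timepoint == "C0"
        ]
        try:
            groups = stratify_by_cutoff(fcs, c1_row.roc.cutoff, records)
            result.survival = SurvivalComparison(
                cutoff=c1_row.roc.cutoff,
                above=km_estimate(groups.above, group="above-cutoff"),
                below=km_estimate(groups.below, group="below-cutoff"),
                logrank=logrank_test(groups.above, groups.below),
            )
        except DegenerateStratification as exc:
            result.survival_skipped = str(exc)
            logger.warning("survival skipped: %s", exc)

    # stage 6: tissue-plasma RAS concordance
    logger.info("stage concordance")
    pairs = [p.tissue_ras for p in cohort if p.tissue_ras is not None]
    if pairs:
        result.concordance = ras_concordance(pairs, alpha)

    # cohort summaries
    result.summaries = {
        "n_patients": len(cohort),
        "n_monitored": len(candidates),
        "n_excluded_no_ctdna": len(excluded),
        "pretreatment_detection_pct": round(
            100.0 * len(candidates) / len(cohort), 2
        )
        if cohort
        else float("nan"),
        "truth_detection_pct": round(detection_rate(cohort), 2) if cohort else float("nan"),
        "gene_frequencies_pct": {
            g: round(v, 2) for g, v in gene_mutation_frequencies(cohort).items()
        }
        if cohort
        else {},
    }

    if outdir is not None:
        _write_reports(result, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# report rendering


def _row_payload(row: DiagnosticRow) -> dict:
    payload = {
        "marker": row.marker,
        "interval": row.interval,
        "n": row.n,
        "n_pd": row.n_pd,
        "n_nonpd": row.n_nonpd,
        "auc": round(row.roc.auc, 3),
        "auc_p": fileio.format_p(row.roc.auc_p),
        "mann_whitney_p": fileio.format_p(row.mw_p),
        "cutoff": round(row.roc.cutoff, 3),
        "tp": row.matrix.tp,
        "fp": row.matrix.fp,
        "tn": row.matrix.tn,
        "fn": row.matrix.fn,
    }
    for name, metric in row.metrics.items():
        if metric.defined:
            est, lo, hi = metric.rounded(1)
            payload[name] = est
            payload[f"{name}_ci"] = f"{lo}-{hi}"
        else:
            payload[name] = None
            payload[f"{name}_ci"] = "undefined"
    return payload


def _write_reports(result: PipelineResult, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    rows = [_row_payload(r) for r in result.rows]
    pd.DataFrame(rows).to_csv(outdir / "table1.tsv", sep="\t", index=False)
    fileio.write_fold_changes(result.fold_changes, outdir / "fold_changes.tsv")
    fileio.write_audit_log(result.audit_rows, outdir / "audit.tsv")

    payload: dict = {
        "diagnostics": rows,
        "diagnostics_skipped": result.skipped_rows,
        "delong_comparisons": [
            {**d, "auc_1": round(d["auc_1"], 3), "auc_2": round(d["auc_2"], 3),
             "p": fileio.format_p(d["p"])}
            for d in result.delong
        ],
        "excluded_no_ctdna": result.excluded,
        "summaries": result.summaries,
        "notes": "No multiple-testing correction is applied across the nine "
        "biomarker/interval combinations.",
    }
    if result.survival is not None:
        surv = result.survival
        payload["survival"] = {
            "cutoff": round(surv.cutoff, 3),
            "n_above": surv.above.n,
            "n_below": surv.below.n,
            "median_pfs_above": _finite_or_str(surv.above.median),
            "median_pfs_below": _finite_or_str(surv.below.median),
            "logrank_chi_square": round(surv.logrank.chi_square, 3),
            "logrank_p": fileio.format_p(surv.logrank.p),
        }
        _write_survival_outputs(surv, outdir)
    else:
        payload["survival"] = {"skipped": result.survival_skipped}
    if result.concordance is not None:
        conc = result.concordance
        payload["concordance"] = {
            "n": conc.matrix.n,
            "n_concordant": conc.n_concordant,
            "tp": conc.matrix.tp,
            "fp": conc.matrix.fp,
            "tn": conc.matrix.tn,
            "fn": conc.matrix.fn,
            **{
                name: (metric.rounded(1)[0] if metric.defined else None)
                for name, metric in conc.metrics.items()
            },
        }
    fileio.write_json(payload, outdir / "report.json")


def _finite_or_str(value: float):
    import math

    return value if math.isfinite(value) else "not reached"


def _write_survival_outputs(surv: SurvivalComparison, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    with plt.rc_context({"svg.hashsalt": "ctdnaflow"}):
        fig, ax = plt.subplots(figsize=(5, 4))
        for est, color in ((surv.below, "tab:blue"), (surv.above, "tab:red")):
            ax.step(
                est.times,
                est.survival,
                where="post",
                color=color,
                label=f"{est.group} (n={est.n})",
            )
        ax.set_xlabel("months since first treatment cycle")
        ax.set_ylabel("progression-free survival")
        ax.set_ylim(0, 1.02)
        ax.legend(loc="upper right", fontsize=8)
        ax.set_title(
            f"PFS by ctDNA log2(C1/C0) cutoff {surv.cutoff:.3f} "
            f"(log-rank p={fileio.format_p(surv.logrank.p)})",
            fontsize=9,
        )
        fig.tight_layout()
        fig.savefig(outdir / "km_pfs.svg")
        plt.close(fig)

    rows = []
    for est in (surv.below, surv.above):
        for t, s in zip(est.times, est.survival):
            rows.append({"group": est.group, "time": t, "survival": s})
    pd.DataFrame(rows).to_csv(outdir / "survival.tsv", sep="\t", index=False)
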