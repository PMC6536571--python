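"""Candidate-mutation selection and longitudinal fold-change tracking.

For each patient the mutation with the maximal allele fraction in the
pretreatment (C0) filtered plasma calls is the candidate target. Its
allele fraction — together with the serum markers CEA and CA19-9 — is
tracked across later draws (C1–C3) as log2 fold changes referenced to
C0, and a patient is classified as predicted progressive disease when
the fold change exceeds a cutoff.

Zero levels are left-censored: values are floored at half the assay
detection limit (ctDNA) or the assay lower quantitation limit (serum
markers) before taking the ratio, keeping log2 finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MARKER_CTDNA = "ctDNA"
MARKER_CEA = "CEA"
MARKER_CA199 = "CA19-9"
MARKERS = (MARKER_CTDNA, MARKER_CEA, MARKER_CA199)

PD = "PD"
NON_PD = "non-PD"


class NoDetectableCtDNA(Exception):
    """Raised when a patient has no filtered pretreatment calls.

    Such patients cannot be monitored and are excluded from the study
    workflow (mirroring the enrollment flow chart).
    """


@dataclass
class FloorLevels:
    """Left-censoring floors, in each marker's native units.

    ctDNA: fraction (default half the 0.5% detection limit);
    CEA: ng/mL; CA19-9: U/mL (assay lower quantitation limits).
    """

    ctdna: float = 0.0025
    cea: float = 0.5
    ca19_9: float = 0.6

    def for_marker(self, marker: str) -> float:
        return {MARKER_CTDNA: self.ctdna, MARKER_CEA: self.cea, MARKER_CA199: self.ca19_9}[
            marker
        ]


@dataclass
class CandidateMutation:
    patient_id: str
    key: tuple[str, int, str, str]
    gene: str
    aa_change: str
    c0_vaf: float


@dataclass
class FoldChange:
    patient_id: str
    marker: str
    from_timepoint: str
    to_timepoint: str
    value: float
    source: str = "filtered"  # ctDNA only: filtered | raw_fallback | floored


def select_candidate(c0_filtered_calls, patient_id: str = "") -> CandidateMutation:
    """The maximal-VAF call among the patient's filtered C0 calls.

    Deterministic: ties on VAF break toward higher alt-read support,
    then the lexicographically smallest (chrom, pos, ref, alt) key, so
    the result is invariant to input ordering.
    """
    calls = list(c0_filtered_calls)
    if not calls:
        raise NoDetectableCtDNA(
            f"patient {patient_id or '<unknown>'}: no filtered pretreatment calls"
        )
    best = sorted(calls, key=lambda c: (-c.vaf, -c.alt_count) + c.key)[0]
    return CandidateMutation(
        patient_id=patient_id,
        key=best.key,
        gene=best.gene,
        aa_change=best.aa_change,
        c0_vaf=best.vaf,
    )


def log2_fold_change(numerator: float, denominator: float, floor: float) -> float:
    """log2(max(numerator, floor) / max(denominator, floor)).

    Both levels are floored before the ratio so a fully cleared marker
    yields a finite (floored) decline rather than -inf.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if numerator < 0 or denominator < 0:
        raise ValueError("marker levels must be non-negative")
    return math.log2(max(numerator, floor) / max(denominator, floor))


def ctdna_level(sample, candidate_key, min_fallback_alt: int = 3) -> tuple[float, str]:
    """Candidate allele fraction in one sample, with raw-read fallback.

    Prefers the filtered call; if the candidate fell below the 0.5%
    filter gate but raw alt reads remain (>= ``min_fallback_alt``), the
    raw VAF is used so genuine residual signal is not zeroed. Returns
    ``(level, source)`` where source is one of ``filtered``,
    ``raw_fallback`` or ``floored`` (level 0.0, to be floored later).
    """
    filtered = sample.filtered_calls or []
    for call in filtered:
        if call.key == candidate_key:
            return call.vaf, "filtered"
    for call in sample.raw_calls:
        if call.key == candidate_key and call.alt_count >= min_fallback_alt:
            return call.vaf, "raw_fallback"
    return 0.0, "floored"


def track_patient(
    patient,
    candidate: CandidateMutation,
    floors: FloorLevels | None = None,
    reference: str = "baseline",
    min_fallback_alt: int = 3,
) -> list[FoldChange]:
    """All log2 fold changes for one patient (ctDNA, CEA, CA19-9).

    One record per available later timepoint per marker; missing draws
    or missing serum values yield no record. ``reference="baseline"``
    computes log2(Ct/C0) (the default used throughout the analysis);
    ``reference="adjacent"`` computes log2(Ct/Ct-1).
    """
    if reference not in ("baseline", "adjacent"):
        raise ValueError(f"unknown reference {reference!r}")
    floors = floors or FloorLevels()
    timepoints = sorted(patient.samples)  # C0 < C1 < C2 < C3 lexicographically
    if "C0" not in timepoints:
        raise ValueError(f"patient {patient.patient_id} has no pretreatment (C0) sample")

    levels: dict[str, dict[str, tuple[float, str]]] = {m: {} for m in MARKERS}
    for tp in timepoints:
        sample = patient.samples[tp]
        level, source = ctdna_level(sample, candidate.key, min_fallback_alt)
        levels[MARKER_CTDNA][tp] = (level, source)
        if sample.cea is not None and not math.isnan(sample.cea):
            levels[MARKER_CEA][tp] = (sample.cea, "measured")
        if sample.ca19_9 is not None and not math.isnan(sample.ca19_9):
            levels[MARKER_CA199][tp] = (sample.ca19_9, "measured")

    out: list[FoldChange] = []
    for marker in MARKERS:
        floor = floors.for_marker(marker)
        series = levels[marker]
        if "C0" not in series:
            continue
        later = [tp for tp in timepoints if tp != "C0" and tp in series]
        for tp in later:
            if reference == "baseline":
                ref_tp = "C0"
            else:
                idx = timepoints.index(tp)
                ref_tp = timepoints[idx - 1]
                if ref_tp not in series:
                    continue
            value = log2_fold_change(series[tp][0], series[ref_tp][0], floor)
            source = series[tp][1] if marker == MARKER_CTDNA else "measured"
            out.append(
                FoldChange(
                    patient_id=patient.patient_id,
                    marker=marker,
                    from_timepoint=ref_tp,
                    to_timepoint=tp,
                    value=value,
                    source=source,
                )
            )
    return out


def classify(fc_value: float, cutoff: float) -> str:
    """Predicted PD iff the fold change strictly exceeds the cutoff.

    The cutoff may be infinite (a degenerate ROC picks -inf, predicting
    PD for everyone); the fold change itself must be finite.
    """
    if not math.isfinite(fc_value) or math.isnan(cutoff):
        raise ValueError("fold change must be finite and cutoff non-NaN")
    return PD if fc_value > cutoff else NON_PD
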