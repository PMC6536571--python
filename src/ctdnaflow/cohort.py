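"""Patient-level records and cohort-level descriptive summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

from .calls import VariantCall
from .concordance import PairedRasStatus

TIMEPOINTS = ("C0", "C1", "C2", "C3")


@dataclass
class TimepointSample:
    """One plasma draw: raw calls, post-filter calls and serum markers."""

    timepoint: str
    avg_depth: float
    raw_calls: list[VariantCall] = field(default_factory=list)
    filtered_calls: list[VariantCall] | None = None
    cea: float | None = None  # ng/mL
    ca19_9: float | None = None  # U/mL


@dataclass
class PatientRecord:
    """One monitored patient.

    ``truth_mutations`` maps each present timepoint to the simulated
    ground-truth somatic allele fractions (site key -> VAF); it is empty
    for real data and for patients with no detectable pretreatment
    ctDNA. ``response`` is the radiologic label after cycle 4.
    """

    patient_id: str
    index: int
    response: str  # "PD" | "non-PD"
    pfs_months: float
    pfs_event: bool
    samples: dict[str, TimepointSample] = field(default_factory=dict)
    pbl_calls: list[VariantCall] = field(default_factory=list)
    truth_mutations: dict[str, dict[tuple, float]] = field(default_factory=dict)
    mutated_genes: tuple[str, ...] = ()
    tissue_ras: PairedRasStatus | None = None

    @property
    def is_pd(self) -> bool:
        return self.response == "PD"

    @property
    def timepoints_present(self) -> list[str]:
        return sorted(self.samples)

    @property
    def has_detectable_ctdna(self) -> bool:
        return bool(self.truth_mutations.get("C0"))

    def truth_candidate_key(self) -> tuple | None:
        """Site key of the maximal-VAF ground-truth C0 mutation."""
        c0 = self.truth_mutations.get("C0")
        if not c0:
            return None
        return sorted(c0, key=lambda k: (-c0[k],) + k)[0]

    def truth_candidate_vaf(self, timepoint: str) -> float | None:
        key = self.truth_candidate_key()
        if key is None:
            return None
        series = self.truth_mutations.get(timepoint)
        return None if series is None else series.get(key)


def detection_rate(cohort: list[PatientRecord]) -> float:
    """Percent of patients with any detectable pretreatment ctDNA mutation."""
    if not cohort:
        raise ValueError("detection_rate requires a non-empty cohort")
    detected = sum(p.has_detectable_ctdna for p in cohort)
    return 100.0 * detected / len(cohort)


def gene_mutation_frequencies(cohort: list[PatientRecord]) -> dict[str, float]:
    """Percent of patients carrying a pretreatment mutation, per gene."""
    if not cohort:
        raise ValueError("gene_mutation_frequencies requires a non-empty cohort")
    counts: dict[str, int] = {}
    for patient in cohort:
        for gene in set(patient.mutated_genes):
            counts[gene] = counts.get(gene, 0) + 1
    return {gene: 100.0 * k / len(cohort) for gene, k in sorted(counts.items())}
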