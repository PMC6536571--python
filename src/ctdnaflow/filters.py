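"""Four-step somatic filtering of deep amplicon-panel plasma variant calls.

The pipeline turns raw caller output into final somatic ctDNA calls:

1. primary threshold filter — sample average depth, per-variant coverage,
   variant allele fraction and error-model p-value;
2. strand-bias filter — a two-sided Fisher exact test on per-strand
   alt/ref read counts, with a minor-strand-fraction guard (a
   quantitative replacement for manual inspection of pileups);
3. hotspot filter — restriction to the panel's recurrent-mutation
   whitelist at allele level;
4. germline filter — subtraction of calls present in the patient's
   matched peripheral-blood-leukocyte (PBL) sample.

Every dropped call is recorded in an audit log with the step and reason,
so filter order is observable and recall per contaminant class testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .calls import VariantCall

STEP_PRIMARY = "primary"
STEP_STRAND = "strand_bias"
STEP_HOTSPOT = "hotspot"
STEP_GERMLINE = "germline"
PIPELINE_STEPS = (STEP_PRIMARY, STEP_STRAND, STEP_HOTSPOT, STEP_GERMLINE)


@dataclass
class FilterThresholds:
    """Thresholds of the four filtering steps.

    All primary-filter comparisons are strict, matching the published
    inequalities (depth > 10,000; variant coverage > 10; VAF > 0.5%;
    p < 0.01). ``min_vaf`` should not be set below the calibrated assay
    limit of detection.
    """

    min_avg_depth: float = 10_000.0
    min_variant_coverage: int = 10
    min_vaf: float = 0.005
    max_p: float = 0.01
    strand_bias_p: float = 0.001
    min_strand_fraction: float = 0.1
    min_pbl_vaf_for_germline: float = 0.01
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "min_avg_depth",
            "min_variant_coverage",
            "min_vaf",
            "max_p",
            "strand_bias_p",
            "min_strand_fraction",
            "min_pbl_vaf_for_germline",
            "error_rate",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {value}")


def call_pvalue(alt_count: int, depth: int, error_rate: float) -> float:
    """One-sided exact binomial tail P(X >= alt_count | n=depth, p=error_rate).

    Stand-in error model for the proprietary caller's per-site p-value:
    the probability of observing at least the seen number of alt reads
    if the site carried no variant and every alt read were a sequencing
    error at the fixed per-base rate.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if not 0 < error_rate < 1:
        raise ValueError(f"error_rate must be in (0, 1), got {error_rate}")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count {alt_count} outside [0, {depth}]")
    return float(stats.binom.sf(alt_count - 1, depth, error_rate))


def _primary_reason(
    call: VariantCall, sample_avg_depth: float, t: FilterThresholds
) -> str | None:
    """Reason the primary filter drops ``call``, or None if it passes."""
    if not sample_avg_depth > t.min_avg_depth:
        return f"sample average depth {sample_avg_depth:g} <= {t.min_avg_depth:g}"
    if not call.alt_count > t.min_variant_coverage:
        return f"variant coverage {call.alt_count} <= {t.min_variant_coverage}"
    if not call.vaf > t.min_vaf:
        return f"VAF {call.vaf:.6f} <= {t.min_vaf:g}"
    if not call.p_value < t.max_p:
        return f"p-value {call.p_value:.3g} >= {t.max_p:g}"
    return None


def primary_filter(
    calls: Sequence[VariantCall],
    sample_avg_depth: float,
    thresholds: FilterThresholds | None = None,
) -> list[VariantCall]:
    """Keep calls passing the strict depth / coverage / VAF / p thresholds."""
    t = thresholds or FilterThresholds()
    return [c for c in calls if _primary_reason(c, sample_avg_depth, t) is None]


def strand_bias_filter(
    call: VariantCall,
    strand_bias_p: float = 0.001,
    min_strand_fraction: float = 0.1,
) -> tuple[bool, str | None]:
    """Decide whether a call is a strand-specific artifact.

    Two-sided Fisher exact test on [[alt_fwd, alt_rev], [ref_fwd, ref_rev]].
    The call is dropped only when the test is significant *and* the minor
    strand carries less than ``min_strand_fraction`` of the alt reads —
    the guard keeps genuine low-coverage variants with mild imbalance.

    Returns ``(keep, reason)``; ``reason`` is None when kept.
    """
    if call.alt_count == 0:
        raise ValueError("strand-bias test undefined for alt_count == 0")
    table = [[call.alt_fwd, call.alt_rev], [call.ref_fwd, call.ref_rev]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    minor_fraction = min(call.alt_fwd, call.alt_rev) / call.alt_count
    if p < strand_bias_p and minor_fraction < min_strand_fraction:
        return False, (
            f"strand bias: Fisher p={p:.3g} < {strand_bias_p:g}, "
            f"minor strand fraction {minor_fraction:.3f} < {min_strand_fraction:g}"
        )
    return True, None


def _whitelist_keys(whitelist: Iterable) -> set[tuple[str, int, str, str]]:
    """Normalize a whitelist of keys or key-bearing objects to a key set."""
    keys = set()
    for entry in whitelist:
        key = entry.key if hasattr(entry, "key") else tuple(entry)
        keys.add((str(key[0]), int(key[1]), str(key[2]), str(key[3])))
    return keys


def hotspot_filter(calls: Sequence[VariantCall], whitelist: Iterable) -> list[VariantCall]:
    """Retain calls whose (chrom, pos, ref, alt) key is on the hotspot whitelist."""
    keys = _whitelist_keys(whitelist)
    if not keys:
        warnings.warn("hotspot whitelist is empty; all calls removed", stacklevel=2)
        return []
    return [c for c in calls if c.key in keys]


def germline_filter(
    plasma_calls: Sequence[VariantCall],
    pbl_calls: Sequence[VariantCall],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition plasma calls into (somatic, germline) by PBL comparison.

    A plasma call is germline iff the matched PBL sample carries the
    identical allele at or above ``min_pbl_vaf_for_germline``.
    """
    t = thresholds or FilterThresholds()
    germline_keys = {
        c.key for c in pbl_calls if c.vaf >= t.min_pbl_vaf_for_germline
    }
    somatic = [c for c in plasma_calls if c.key not in germline_keys]
    germline = [c for c in plasma_calls if c.key in germline_keys]
    return somatic, germline


@dataclass
class AuditEntry:
    call: VariantCall
    step: str
    reason: str


@dataclass
class FilterResult:
    passed: list[VariantCall]
    audit: list[AuditEntry] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.audit)


def filter_pipeline(
    raw_calls: Sequence[VariantCall],
    pbl_calls: Sequence[VariantCall],
    sample_avg_depth: float,
    whitelist: Iterable,
    thresholds: FilterThresholds | None = None,
) -> FilterResult:
    """Apply the four filters in order, recording every drop with its step."""
    t = thresholds or FilterThresholds()
    audit: list[AuditEntry] = []

    kept: list[VariantCall] = []
    for call in raw_calls:
        reason = _primary_reason(call, sample_avg_depth, t)
        if reason is None:
            kept.append(call)
        else:
            audit.append(AuditEntry(call, STEP_PRIMARY, reason))

    survivors: list[VariantCall] = []
    for call in kept:
        keep, reason = strand_bias_filter(call, t.strand_bias_p, t.min_strand_fraction)
        if keep:
            survivors.append(call)
        else:
            audit.append(AuditEntry(call, STEP_STRAND, reason or ""))
    kept = survivors

    keys = _whitelist_keys(whitelist)
    if not keys:
        warnings.warn("hotspot whitelist is empty; all calls removed", stacklevel=2)
    survivors = []
    for call in kept:
        if call.key in keys:
            survivors.append(call)
        else:
            audit.append(AuditEntry(call, STEP_HOTSPOT, "not a panel hotspot"))
    kept = survivors

    somatic, germline = germline_filter(kept, pbl_calls, t)
    for call in germline:
        audit.append(
            AuditEntry(call, STEP_GERMLINE, "allele present in matched PBL sample")
        )

    return FilterResult(passed=somatic, audit=audit)


@dataclass
class ReadLengthQC:
    """Result of the read-length quality screen.

    ``kept_fraction`` is NaN when no reads were supplied (the 0/0 case).
    """

    mask: np.ndarray
    n_kept: int
    n_total: int
    kept_fraction: float


def read_length_qc(
    read_lengths: Sequence[int], min_bp: int = 60, max_bp: int = 160
) -> ReadLengthQC:
    """Keep reads with length in [min_bp, max_bp] (defaults 60–160 bp)."""
    lengths = np.asarray(read_lengths)
    if lengths.size and (lengths <= 0).any():
        raise ValueError("read lengths must be positive")
    mask = (lengths >= min_bp) & (lengths <= max_bp) if lengths.size else np.zeros(0, bool)
    n_kept = int(mask.sum())
    n_total = int(lengths.size)
    fraction = n_kept / n_total if n_total else math.nan
    return ReadLengthQC(mask=mask, n_kept=n_kept, n_total=n_total, kept_fraction=fraction)
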