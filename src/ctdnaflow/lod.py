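"""Assay limit of detection from reference-standard replicates.

The detection limit is the smallest nominal mutant fraction whose
replicate measurements completely separate from the negative-control
replicates — equivalently, a zero-false-positive threshold over the
observed background. No parametric limit-of-blank model is fitted.
"""

from __future__ import annotations

from typing import Sequence

#: Sentinel returned when no nominal level separates from background.
NOT_DETERMINED = None


def separation_check(positives: Sequence[float], negatives: Sequence[float]) -> bool:
    """True iff every positive measurement exceeds every negative one.

    Strict: a tie between the smallest positive and the largest negative
    counts as overlap (a shared value cannot be called without false
    positives).
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("separation_check requires non-empty positive and negative lists")
    return min(positives) > max(negatives)


def determine_detection_limit(standards) -> float | None:
    """Smallest nominal fraction completely separated from negative controls.

    ``standards`` is a :class:`~ctdnaflow.synthetic.ReferenceStandardSet`
    (or anything with ``nominal_fractions`` and a ``measured`` mapping).
    Returns :data:`NOT_DETERMINED` if no level separates.
    """
    fractions = sorted(standards.nominal_fractions)
    if not fractions or fractions[0] != 0:
        raise ValueError("standards must include a zero-fraction negative-control level")
    negatives = standards.measured[fractions[0]]
    for fraction in fractions[1:]:
        if separation_check(standards.measured[fraction], negatives):
            return fraction
    return NOT_DETERMINED
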