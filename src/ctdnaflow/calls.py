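"""Variant-call record shared by the simulator, the filters and VCF I/O."""

from __future__ import annotations

import math
from dataclasses import dataclass

# Ground-truth classes attached by the simulator so filter recall can be
# measured against known labels. Real data carries no such tag (None).
SOMATIC = "somatic"
GERMLINE = "germline"
ARTIFACT = "artifact"
NOISE = "noise"


@dataclass
class VariantCall:
    """One called variant at a panel site.

    Coordinates follow the VCF convention (1-based, explicit ref/alt
    alleles; multiallelic records are split into one call per alt).
    ``p_value`` is the probability of seeing at least ``alt_count``
    alt reads under the per-base sequencing-error model.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    p_value: float = 1.0
    gene: str = ""
    aa_change: str = ""
    truth_class: str | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )
        if self.alt_fwd + self.alt_rev != self.alt_count:
            raise ValueError(
                "strand counts inconsistent: "
                f"alt_fwd+alt_rev={self.alt_fwd + self.alt_rev} != alt_count={self.alt_count}"
            )
        if self.alt_fwd < 0 or self.alt_rev < 0 or self.ref_fwd < 0 or self.ref_rev < 0:
            raise ValueError("strand counts must be non-negative")
        if self.ref_fwd + self.ref_rev + self.alt_count > self.depth:
            raise ValueError("ref + alt read counts exceed depth")
        if not math.isfinite(self.p_value) or not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")

    @property
    def vaf(self) -> float:
        """Variant allele fraction: alt-supporting reads / total reads."""
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-level identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        """Human-readable 'GENE p.change' label."""
        return f"{self.gene} {self.aa_change}".strip()


def balanced_call(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    depth: int,
    alt_count: int,
    p_value: float = 0.0,
    gene: str = "",
    aa_change: str = "",
    truth_class: str | None = None,
) -> VariantCall:
    """Convenience constructor with an even forward/reverse strand split."""
    ref_count = depth - alt_count
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=depth,
        alt_count=alt_count,
        alt_fwd=alt_count // 2,
        alt_rev=alt_count - alt_count // 2,
        ref_fwd=ref_count // 2,
        ref_rev=ref_count - ref_count // 2,
        p_value=p_value,
        gene=gene,
        aa_change=aa_change,
        truth_class=truth_class,
    )
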