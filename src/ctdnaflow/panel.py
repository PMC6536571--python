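"""Synthetic 50-gene amplicon panel: hotspot whitelist used throughout.

The site list is a synthetic stand-in for a commercial colorectal-cancer
panel's hotspot manifest: recurrent substitutions in the genes the assay
targets, at plausible (not authoritative) genomic coordinates. Three
disjoint pools keep simulated call classes separable: somatic hotspots
(grouped by gene), sites reserved for injected germline polymorphism
contaminants, and sites reserved for injected strand-artifact
contaminants. All pools belong to the whitelist, so contaminants are
removed by the strand-bias or PBL-subtraction steps, never accidentally
by the hotspot step.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class HotspotSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    aa_change: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.gene} {self.aa_change}"


SOMATIC_SITES: tuple[HotspotSite, ...] = (
    HotspotSite("chr17", 7578406, "C", "T", "TP53", "R175H"),
    HotspotSite("chr17", 7577538, "C", "T", "TP53", "R248Q"),
    HotspotSite("chr17", 7577120, "C", "T", "TP53", "R273H"),
    HotspotSite("chr17", 7577548, "C", "T", "TP53", "G245S"),
    HotspotSite("chr12", 25398284, "C", "T", "KRAS", "G12D"),
    HotspotSite("chr12", 25398284, "C", "A", "KRAS", "G12V"),
    HotspotSite("chr12", 25398281, "C", "T", "KRAS", "G13D"),
    HotspotSite("chr12", 25380275, "T", "G", "KRAS", "Q61H"),
    HotspotSite("chr1", 115256530, "G", "T", "NRAS", "Q61K"),
    HotspotSite("chr1", 115258744, "C", "T", "NRAS", "A59T"),
    HotspotSite("chr5", 112175240, "C", "T", "APC", "R1450*"),
    HotspotSite("chr5", 112174631, "C", "T", "APC", "R1114*"),
    HotspotSite("chr5", 112173917, "C", "T", "APC", "R876*"),
    HotspotSite("chr3", 178936091, "G", "A", "PIK3CA", "E545K"),
    HotspotSite("chr3", 178952085, "A", "G", "PIK3CA", "H1047R"),
    HotspotSite("chr7", 140453136, "A", "T", "BRAF", "V600E"),
    HotspotSite("chr7", 55259515, "T", "G", "EGFR", "L858R"),
    HotspotSite("chr18", 48591918, "G", "A", "SMAD4", "R361H"),
    HotspotSite("chr4", 153247289, "G", "A", "FBXW7", "R465C"),
    HotspotSite("chr3", 41266124, "C", "T", "CTNNB1", "S45F"),
)

#: Panel sites reserved for injected germline polymorphism contaminants.
GERMLINE_RESERVED_SITES: tuple[HotspotSite, ...] = (
    HotspotSite("chr17", 7579472, "G", "C", "TP53", "P72R"),
    HotspotSite("chr5", 112176756, "T", "A", "APC", "V1822D"),
    HotspotSite("chr4", 55972974, "T", "A", "KDR", "Q472H"),
    HotspotSite("chr2", 212578380, "T", "A", "ERBB4", "I241I"),
)

#: Panel sites reserved for injected strand-artifact contaminants.
ARTIFACT_RESERVED_SITES: tuple[HotspotSite, ...] = (
    HotspotSite("chr13", 28610183, "A", "G", "FLT3", "D835G"),
    HotspotSite("chr11", 534242, "A", "G", "HRAS", "H27H"),
    HotspotSite("chr10", 43613843, "G", "T", "RET", "M918I"),
    HotspotSite("chr19", 1221293, "G", "A", "STK11", "D194N"),
)

ALL_PANEL_SITES: tuple[HotspotSite, ...] = (
    SOMATIC_SITES + GERMLINE_RESERVED_SITES + ARTIFACT_RESERVED_SITES
)

#: Genes used when a patient carries none of the prevalence-tracked genes.
FILLER_GENES = ("EGFR", "SMAD4", "FBXW7", "CTNNB1")


def sites_by_gene() -> dict[str, list[HotspotSite]]:
    out: dict[str, list[HotspotSite]] = {}
    for site in SOMATIC_SITES:
        out.setdefault(site.gene, []).append(site)
    return out


def default_whitelist() -> list[HotspotSite]:
    """The full hotspot whitelist (somatic + reserved contaminant sites)."""
    return list(ALL_PANEL_SITES)
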