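"""File formats: VCF 4.2 call sets and the tabular study files.

Variant calls round-trip through sites-only VCF with INFO fields
``DP`` (total depth), ``AO`` (alt reads), ``AF`` (allele fraction),
``SAF``/``SAR`` (alt reads forward/reverse), ``RF``/``RR`` (ref reads
forward/reverse), ``PV`` (error-model p-value, stored as a string to
survive the float formatting round trip), ``GENE``, ``AA`` and the
simulator's ``CLASS`` tag. Multiallelic records are split into one
call per alt on read.

Tabular interfaces are TSV throughout: patient metadata, serum markers,
the hotspot whitelist, fold changes, reference standards and the
performance table (with a machine-readable JSON twin).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .calls import VariantCall
from .cohort import PatientRecord, TimepointSample
from .concordance import PairedRasStatus
from .panel import HotspotSite
from .synthetic import ReferenceStandardSet


class VcfFormatError(ValueError):
    """Raised for malformed VCF input, naming the offending line."""


_PER_ALT = [
    ("AO", "Integer", "Alt-supporting read count"),
    ("SAF", "Integer", "Alt reads on the forward strand"),
    ("SAR", "Integer", "Alt reads on the reverse strand"),
    ("AF", "Float", "Alt allele fraction (AO/DP)"),
    ("PV", "String", "Error-model p-value (repr round-trip)"),
    ("GENE", "String", "Gene symbol"),
    ("AA", "String", "Amino-acid change"),
    ("CLASS", "String", "Simulated ground-truth class"),
]
_PER_SITE = [
    ("DP", "Integer", "Total read depth at the site"),
    ("RF", "Integer", "Ref reads on the forward strand"),
    ("RR", "Integer", "Ref reads on the reverse strand"),
]

_CONTIG_LENGTH = 250_000_000


def _vcf_header(calls: Sequence[VariantCall]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    seen: list[str] = []
    for call in calls:
        if call.chrom not in seen:
            seen.append(call.chrom)
    for chrom in seen:
        header.contigs.add(chrom, length=_CONTIG_LENGTH)
    for name, vtype, desc in _PER_SITE:
        header.info.add(name, 1, vtype, desc)
    for name, vtype, desc in _PER_ALT:
        header.info.add(name, "A", vtype, desc)
    return header


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as an uncompressed sites-only VCF 4.2 (one record per call)."""
    path = Path(path)
    header = _vcf_header(calls)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: c.key):
            record = vcf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            record.info["DP"] = call.depth
            record.info["RF"] = call.ref_fwd
            record.info["RR"] = call.ref_rev
            record.info["AO"] = (call.alt_count,)
            record.info["SAF"] = (call.alt_fwd,)
            record.info["SAR"] = (call.alt_rev,)
            record.info["AF"] = (call.vaf,)
            record.info["PV"] = (repr(call.p_value),)
            if call.gene:
                record.info["GENE"] = (call.gene,)
            if call.aa_change:
                record.info["AA"] = (call.aa_change.replace(" ", "_"),)
            if call.truth_class:
                record.info["CLASS"] = (call.truth_class,)
            vcf.write(record)


def _info_alt(record, name, index, default=None):
    try:
        value = record.info.get(name)
    except (KeyError, ValueError):  # field absent from the header entirely
        return default
    if value is None:
        return default
    if isinstance(value, tuple):
        return value[index] if index < len(value) else default
    return value if index == 0 else default


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a VCF into calls, splitting multiallelic records per alt."""
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    if not first.startswith("##fileformat=VCF"):
        raise VcfFormatError(f"{path}: line 1 must be a ##fileformat=VCF header line")
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            depth = int(record.info["DP"])
            ref_fwd = int(record.info.get("RF", 0))
            ref_rev = int(record.info.get("RR", 0))
            for i, alt in enumerate(record.alts or ()):
                alt_count = int(_info_alt(record, "AO", i, 0))
                aa = _info_alt(record, "AA", i, "") or ""
                calls.append(
                    VariantCall(
                        chrom=record.chrom,
                        pos=record.pos,
                        ref=record.ref,
                        alt=str(alt),
                        depth=depth,
                        alt_count=alt_count,
                        alt_fwd=int(_info_alt(record, "SAF", i, 0)),
                        alt_rev=int(_info_alt(record, "SAR", i, 0)),
                        ref_fwd=ref_fwd,
                        ref_rev=ref_rev,
                        p_value=float(_info_alt(record, "PV", i, "1.0")),
                        gene=_info_alt(record, "GENE", i, "") or "",
                        aa_change=aa.replace("_", " "),
                        truth_class=_info_alt(record, "CLASS", i, None),
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# whitelist and standards tables


def write_whitelist(sites: Iterable[HotspotSite], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "gene": s.gene,
                "aa_change": s.aa_change,
            }
            for s in sites
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_whitelist(path: str | Path) -> list[HotspotSite]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        HotspotSite(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene if isinstance(row.gene, str) else "",
            aa_change=row.aa_change if isinstance(row.aa_change, str) else "",
        )
        for row in frame.itertuples()
    ]


def write_standards(standards: ReferenceStandardSet, path: str | Path) -> None:
    rows = []
    for fraction in standards.nominal_fractions:
        for replicate, vaf in enumerate(standards.measured[fraction], start=1):
            rows.append(
                {"nominal_fraction": fraction, "replicate": replicate, "measured_vaf": vaf}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_standards(path: str | Path, depth: int = 10_000) -> ReferenceStandardSet:
    frame = pd.read_csv(path, sep="\t")
    fractions = tuple(sorted(frame["nominal_fraction"].unique()))
    measured = {
        float(f): frame.loc[frame["nominal_fraction"] == f, "measured_vaf"].tolist()
        for f in fractions
    }
    replicates = len(next(iter(measured.values())))
    return ReferenceStandardSet(
        nominal_fractions=tuple(float(f) for f in fractions),
        replicates_per_fraction=replicates,
        depth=depth,
        measured=measured,
    )


# ---------------------------------------------------------------------------
# cohort directory layout


def write_cohort(
    cohort: Sequence[PatientRecord],
    whitelist: Sequence[HotspotSite],
    outdir: str | Path,
) -> None:
    """Write a cohort directory: per-sample VCFs plus metadata tables.

    Layout: ``<id>_<timepoint>.vcf`` and ``<id>_PBL.vcf`` per patient,
    ``patients.tsv`` (response, PFS, tissue RAS), ``serum.tsv`` (CEA and
    CA19-9 per draw) and ``hotspots.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows, serum_rows = [], []
    for patient in cohort:
        for tp, sample in sorted(patient.samples.items()):
            write_vcf(sample.raw_calls, outdir / f"{patient.patient_id}_{tp}.vcf")
            serum_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "timepoint": tp,
                    "avg_depth": sample.avg_depth,
                    "cea": "" if sample.cea is None else sample.cea,
                    "ca19_9": "" if sample.ca19_9 is None else sample.ca19_9,
                }
            )
        write_vcf(patient.pbl_calls, outdir / f"{patient.patient_id}_PBL.vcf")
        ras = patient.tissue_ras
        meta_rows.append(
            {
                "patient_id": patient.patient_id,
                "patient_index": patient.index,
                "response": patient.response,
                "pfs_months": patient.pfs_months,
                "pfs_event": int(patient.pfs_event),
                "tissue_status": "" if ras is None else ras.tissue,
                "tissue_alleles": "" if ras is None else ";".join(sorted(ras.tissue_alleles)),
                "plasma_alleles": "" if ras is None else ";".join(sorted(ras.plasma_alleles)),
                "mutated_genes": ";".join(patient.mutated_genes),
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "patients.tsv", sep="\t", index=False)
    pd.DataFrame(serum_rows).to_csv(outdir / "serum.tsv", sep="\t", index=False)
    write_whitelist(whitelist, outdir / "hotspots.tsv")


def _parse_alleles(text) -> frozenset[str]:
    if not isinstance(text, str) or not text:
        return frozenset()
    return frozenset(text.split(";"))


def read_cohort(indir: str | Path) -> tuple[list[PatientRecord], list[HotspotSite]]:
    """Reconstruct a cohort (raw calls + metadata) from a cohort directory.

    Ground-truth fields that exist only in memory (truth VAF
    trajectories) are not recoverable from disk; call classes survive
    via the VCF ``CLASS`` tag.
    """
    indir = Path(indir)
    meta = pd.read_csv(indir / "patients.tsv", sep="\t")
    serum = pd.read_csv(indir / "serum.tsv", sep="\t")
    whitelist = read_whitelist(indir / "hotspots.tsv")
    patients = []
    for row in meta.itertuples():
        samples: dict[str, TimepointSample] = {}
        for srow in serum[serum["patient_id"] == row.patient_id].itertuples():
            vcf_path = indir / f"{row.patient_id}_{srow.timepoint}.vcf"
            samples[srow.timepoint] = TimepointSample(
                timepoint=srow.timepoint,
                avg_depth=float(srow.avg_depth),
                raw_calls=read_vcf(vcf_path),
                cea=None if pd.isna(srow.cea) else float(srow.cea),
                ca19_9=None if pd.isna(srow.ca19_9) else float(srow.ca19_9),
            )
        tissue_status = row.tissue_status if isinstance(row.tissue_status, str) else ""
        tissue_ras = None
        if tissue_status:
            tissue_ras = PairedRasStatus(
                patient_id=row.patient_id,
                tissue_alleles=_parse_alleles(row.tissue_alleles),
                plasma_alleles=_parse_alleles(row.plasma_alleles),
            )
        genes = row.mutated_genes if isinstance(row.mutated_genes, str) else ""
        patients.append(
            PatientRecord(
                patient_id=row.patient_id,
                index=int(row.patient_index),
                response=row.response,
                pfs_months=float(row.pfs_months),
                pfs_event=bool(row.pfs_event),
                samples=samples,
                pbl_calls=read_vcf(indir / f"{row.patient_id}_PBL.vcf"),
                tissue_ras=tissue_ras,
                mutated_genes=tuple(genes.split(";")) if genes else (),
            )
        )
    return patients, whitelist


# ---------------------------------------------------------------------------
# analysis outputs


def write_fold_changes(fold_changes, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": fc.patient_id,
                "marker": fc.marker,
                "interval": f"{fc.to_timepoint}/{fc.from_timepoint}",
                "value": fc.value,
                "source": fc.source,
            }
            for fc in fold_changes
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_audit_log(audit_rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(audit_rows).to_csv(path, sep="\t", index=False)


def format_p(p: float) -> str:
    """Render p-values for reports; tiny values print as '<0.001'."""
    if math.isnan(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def write_json(payload: dict, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, fixed separators, trailing newline)."""
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
    Path(path).write_text(text + "\n")
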