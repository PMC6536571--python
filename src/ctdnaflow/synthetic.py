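"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a prospective serial ctDNA monitoring study in
metastatic colorectal cancer: ~41 patients drawn at four two-week
timepoints (C0 pretreatment, C1–C3 before cycles 2–4), a ~15% fraction
progressing radiologically after cycle 4, pretreatment candidate allele
fractions lognormal around ~8%, per-cycle multiplicative ctDNA declines
in non-progressors and rises in progressors, serum markers (CEA,
CA19-9) separating one cycle later than ctDNA, monotone missingness of
later draws, matched-PBL germline and strand-artifact contaminant
calls, and 10-replicate reference standards at 0/0.5/1% mutant fraction
for detection-limit calibration.

Determinism: a single root seed; each patient's streams derive from
``SeedSequence(seed, spawn_key=(stream, patient_index))`` so enlarging
the cohort does not reshuffle existing patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from . import panel as _panel
from .calls import ARTIFACT, GERMLINE, NOISE, SOMATIC, VariantCall
from .cohort import PatientRecord, TimepointSample
from .concordance import PairedRasStatus
from .filters import call_pvalue
from .monitoring import NON_PD, PD

_LN2 = math.log(2.0)

#: Pretreatment mutation prevalence per gene, as observed-study fractions
#: of a 41-patient cohort (counts are made exact by rounding n * p).
DEFAULT_GENE_PREVALENCE: dict[str, float] = {
    "TP53": 29 / 41,
    "KRAS": 22 / 41,
    "APC": 20 / 41,
    "PIK3CA": 8 / 41,
    "BRAF": 3 / 41,
    "NRAS": 1 / 41,
}

RAS_GENES = ("KRAS", "NRAS")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    VAF parameters are fractions; fold-change parameters are per-cycle
    additive shifts on the log2 scale; PFS parameters are months.
    ``log2fc_bounds = (nonpd_max, pd_min)`` optionally truncates the
    per-cycle draws to guarantee a known separating threshold between
    the groups (used by cutoff-recovery experiments); the default is
    untruncated.
    """

    n_patients: int = 41
    pd_fraction: float = 6 / 41
    timepoints: tuple[str, ...] = ("C0", "C1", "C2", "C3")
    c0_vaf_log_mean: float = math.log(0.0795)
    c0_vaf_log_sd: float = 1.0
    nonpd_log2fc_mean: float = -1.5
    nonpd_log2fc_sd: float = 0.6
    pd_log2fc_mean: float = 0.5
    pd_log2fc_sd: float = 0.6
    log2fc_bounds: tuple[float, float] | None = None
    dropout_prob_per_timepoint: float = 0.1
    depth: int = 12_000
    error_rate: float = 0.001
    n_germline_contaminants: int = 2
    n_artifact_contaminants: int = 2
    n_noise_contaminants: int = 3
    detectable_fraction: float = 1.0
    gene_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_PREVALENCE)
    )
    # serum markers: lognormal baselines, group separation lagged by one cycle
    cea_baseline_log_mean: float = math.log(20.0)  # ng/mL
    cea_baseline_log_sd: float = 1.0
    ca199_baseline_log_mean: float = math.log(50.0)  # U/mL
    ca199_baseline_log_sd: float = 1.2
    nonpd_serum_log2_mean: float = -0.6
    pd_serum_log2_mean: float = 0.6
    serum_log2_sd: float = 0.9
    serum_lag_cycles: int = 1
    serum_missing_prob: float = 0.08
    # progression-free survival
    pfs_median_pd: float = 2.0
    pfs_median_nonpd: float = 9.0
    censor_months: float = 24.0
    # tissue-plasma RAS pairing structure
    n_tissue_pairs: int = 25
    n_tissue_mutant: int = 15
    n_tissue_concordant_mutant: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                if not math.isfinite(value):
                    raise ValueError(f"config field {f.name} must be finite, got {value}")
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if not 0 <= self.pd_fraction <= 1:
            raise ValueError(f"pd_fraction must be in [0, 1], got {self.pd_fraction}")
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not 0 < self.error_rate < 0.005:
            raise ValueError(f"error_rate must be in (0, 0.005), got {self.error_rate}")
        if not 0 <= self.dropout_prob_per_timepoint < 1:
            raise ValueError(
                "dropout_prob_per_timepoint must be in [0, 1), got "
                f"{self.dropout_prob_per_timepoint}"
            )
        if not 0 <= self.detectable_fraction <= 1:
            raise ValueError(
                f"detectable_fraction must be in [0, 1], got {self.detectable_fraction}"
            )
        if self.timepoints[0] != "C0":
            raise ValueError("timepoints must start with C0")
        if self.log2fc_bounds is not None:
            for v in self.log2fc_bounds:
                if not math.isfinite(v):
                    raise ValueError(f"log2fc_bounds must be finite, got {self.log2fc_bounds}")


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    upper: float | None = None,
    lower: float | None = None,
    max_tries: int = 10_000,
) -> float:
    if sd == 0:
        value = mean
        if (upper is not None and value > upper) or (lower is not None and value < lower):
            raise ValueError("zero-variance draw incompatible with truncation bounds")
        return value
    for _ in range(max_tries):
        value = float(rng.normal(mean, sd))
        if upper is not None and value > upper:
            continue
        if lower is not None and value < lower:
            continue
        return value
    raise ValueError("truncation bounds too tight: rejection sampling failed")


def _draw_c0_vaf(rng: np.random.Generator, config: CohortConfig) -> float:
    for _ in range(1000):
        vaf = float(np.exp(rng.normal(config.c0_vaf_log_mean, config.c0_vaf_log_sd)))
        if 0.0 < vaf <= 0.8:
            return vaf
    return 0.8


def _exact_count_subset(
    rng: np.random.Generator, candidates: list[int], count: int
) -> set[int]:
    count = min(count, len(candidates))
    if count == 0:
        return set()
    return set(rng.choice(candidates, size=count, replace=False).tolist())


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate patient records: truth trajectories, serum series, PFS.

    Exactly ``round(n_patients * pd_fraction)`` patients are labelled PD
    and ``round(n_patients * detectable_fraction)`` carry detectable
    pretreatment ctDNA. Raw variant-call sets are attached separately by
    :func:`generate_raw_calls` / :func:`generate_full_cohort`.
    """
    n = config.n_patients
    if n == 0:
        return []
    cohort_rng = _rng(config.seed, stream=2)

    all_idx = list(range(n))
    detected = _exact_count_subset(
        cohort_rng, all_idx, int(round(n * config.detectable_fraction))
    )
    pd_set = _exact_count_subset(
        cohort_rng, sorted(detected) if detected else all_idx,
        int(round(n * config.pd_fraction)),
    )

    gene_carriers: dict[str, set[int]] = {}
    detected_sorted = sorted(detected)
    for gene, prevalence in config.gene_prevalence.items():
        gene_carriers[gene] = _exact_count_subset(
            cohort_rng, detected_sorted, int(round(n * prevalence))
        )

    sites_by_gene = _panel.sites_by_gene()
    width = max(2, len(str(n)))
    patients: list[PatientRecord] = []
    for i in range(n):
        rng = _rng(config.seed, stream=0, index=i)
        is_pd = i in pd_set
        genes = tuple(g for g in config.gene_prevalence if i in gene_carriers[g])
        if i in detected and not genes:
            genes = (str(rng.choice(_panel.FILLER_GENES)),)

        # ground-truth somatic profile at C0
        c0_truth: dict[tuple, float] = {}
        site_of_key: dict[tuple, _panel.HotspotSite] = {}
        if i in detected:
            candidate_vaf = _draw_c0_vaf(rng, config)
            candidate_gene = str(rng.choice(genes))
            for gene in genes:
                choices = sites_by_gene.get(gene, [])
                if not choices:
                    continue
                site = choices[int(rng.integers(len(choices)))]
                if site.key in c0_truth:
                    continue
                vaf = (
                    candidate_vaf
                    if gene == candidate_gene
                    else candidate_vaf * float(rng.uniform(0.25, 0.9))
                )
                c0_truth[site.key] = vaf
                site_of_key[site.key] = site

        # per-cycle log2 shifts, compounded; same tumor-burden factor for all sites
        mean = config.pd_log2fc_mean if is_pd else config.nonpd_log2fc_mean
        sd = config.pd_log2fc_sd if is_pd else config.nonpd_log2fc_sd
        upper = lower = None
        if config.log2fc_bounds is not None:
            nonpd_max, pd_min = config.log2fc_bounds
            upper, lower = (None, pd_min) if is_pd else (nonpd_max, None)
        n_cycles = len(config.timepoints) - 1
        steps = [
            _truncated_normal(rng, mean, sd, upper=upper, lower=lower)
            for _ in range(n_cycles)
        ]

        truth: dict[str, dict[tuple, float]] = {"C0": dict(c0_truth)}
        factor = 1.0
        for t, tp in enumerate(config.timepoints[1:], start=1):
            factor *= 2.0 ** steps[t - 1]
            truth[tp] = {
                key: min(vaf * factor, 0.95) for key, vaf in c0_truth.items()
            }

        # monotone missingness of later draws
        present = [config.timepoints[0]]
        for tp in config.timepoints[1:]:
            if rng.uniform() < config.dropout_prob_per_timepoint:
                break
            present.append(tp)

        # serum markers: group separation begins after serum_lag_cycles
        serum_mean = config.pd_serum_log2_mean if is_pd else config.nonpd_serum_log2_mean
        baselines = {
            "cea": float(
                np.exp(rng.normal(config.cea_baseline_log_mean, config.cea_baseline_log_sd))
            ),
            "ca19_9": float(
                np.exp(rng.normal(config.ca199_baseline_log_mean, config.ca199_baseline_log_sd))
            ),
        }
        serum: dict[str, dict[str, float | None]] = {}
        for name, baseline in baselines.items():
            level = baseline
            series: dict[str, float | None] = {}
            for t, tp in enumerate(config.timepoints):
                if t > 0:
                    step_mean = serum_mean if t > config.serum_lag_cycles else 0.0
                    level *= 2.0 ** float(rng.normal(step_mean, config.serum_log2_sd))
                missing = rng.uniform() < config.serum_missing_prob
                series[tp] = None if missing else level
            serum[name] = series

        # progression-free survival: group-specific exponential, censored
        median = config.pfs_median_pd if is_pd else config.pfs_median_nonpd
        raw_time = float(rng.exponential(median / _LN2))
        raw_time = max(raw_time, 0.1)
        event = raw_time <= config.censor_months
        pfs = raw_time if event else config.censor_months

        samples = {
            tp: TimepointSample(
                timepoint=tp,
                avg_depth=float(config.depth),
                cea=serum["cea"][tp],
                ca19_9=serum["ca19_9"][tp],
            )
            for tp in present
        }
        truth = {tp: truth[tp] for tp in present}

        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                index=i,
                response=PD if is_pd else NON_PD,
                pfs_months=pfs,
                pfs_event=event,
                samples=samples,
                truth_mutations=truth,
                mutated_genes=genes if i in detected else (),
            )
        )

    _assign_tissue_ras(patients, cohort_rng, config)
    return patients


def _plasma_ras_alleles(patient: PatientRecord) -> frozenset[str]:
    labels = set()
    site_by_key = {s.key: s for s in _panel.SOMATIC_SITES}
    for key in patient.truth_mutations.get("C0", {}):
        site = site_by_key.get(key)
        if site is not None and site.gene in RAS_GENES:
            labels.add(site.label)
    return frozenset(labels)


def _assign_tissue_ras(
    patients: list[PatientRecord], rng: np.random.Generator, config: CohortConfig
) -> None:
    """Pair a subset of patients with tissue RAS results.

    Structure mirrors the study conditions: among ``n_tissue_pairs``
    paired patients, ``n_tissue_mutant`` are tissue-mutant of whom
    ``n_tissue_concordant_mutant`` have all tissue alleles detected in
    plasma (the remainder are plasma misses), and the rest are
    wild-type in both compartments. Assignment is best-effort when the
    cohort is too small to honor the requested counts.
    """
    if config.n_tissue_pairs <= 0:
        return
    ras_mutant = [p for p in patients if _plasma_ras_alleles(p)]
    ras_wild = [p for p in patients if not _plasma_ras_alleles(p)]
    rng.shuffle(ras_mutant)
    rng.shuffle(ras_wild)

    n_concordant = min(config.n_tissue_concordant_mutant, len(ras_mutant))
    n_missed = min(config.n_tissue_mutant - n_concordant, max(len(ras_wild) - 1, 0))
    n_wild = min(
        config.n_tissue_pairs - n_concordant - n_missed, len(ras_wild) - n_missed
    )

    for p in ras_mutant[:n_concordant]:
        alleles = _plasma_ras_alleles(p)
        p.tissue_ras = PairedRasStatus(
            patient_id=p.patient_id, tissue_alleles=alleles, plasma_alleles=alleles
        )
    missed = ras_wild[:n_missed]
    for p in missed:
        p.tissue_ras = PairedRasStatus(
            patient_id=p.patient_id,
            tissue_alleles=frozenset({"KRAS G12D"}),
            plasma_alleles=frozenset(),
        )
    for p in ras_wild[n_missed : n_missed + max(n_wild, 0)]:
        p.tissue_ras = PairedRasStatus(
            patient_id=p.patient_id, tissue_alleles=frozenset(), plasma_alleles=frozenset()
        )


# ---------------------------------------------------------------------------
# raw variant-call simulation


def _binom_call(
    rng: np.random.Generator,
    site_key: tuple,
    depth: int,
    p_true: float,
    error_rate: float,
    gene: str = "",
    aa_change: str = "",
    truth_class: str = SOMATIC,
    minor_strand_fraction: float | None = None,
) -> VariantCall | None:
    """Sample one call at a site; None when no alt read is drawn."""
    alt = int(rng.binomial(depth, min(max(p_true, 0.0), 1.0)))
    if alt == 0:
        return None
    if minor_strand_fraction is None:
        alt_fwd = int(rng.binomial(alt, 0.5))
    else:
        minor = int(round(alt * minor_strand_fraction))
        alt_fwd = minor if rng.uniform() < 0.5 else alt - minor
    ref = depth - alt
    ref_fwd = int(rng.binomial(ref, 0.5))
    chrom, pos, ref_allele, alt_allele = site_key
    return VariantCall(
        chrom=str(chrom),
        pos=int(pos),
        ref=str(ref_allele),
        alt=str(alt_allele),
        depth=depth,
        alt_count=alt,
        alt_fwd=alt_fwd,
        alt_rev=alt - alt_fwd,
        ref_fwd=ref_fwd,
        ref_rev=ref - ref_fwd,
        p_value=call_pvalue(alt, depth, error_rate),
        gene=gene,
        aa_change=aa_change,
        truth_class=truth_class,
    )


_BASES = ("A", "C", "G", "T")


def _random_offpanel_site(rng: np.random.Generator, taken: set[tuple]) -> tuple:
    while True:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        if ref == alt:
            continue
        key = (chrom, pos, ref, alt)
        if key not in taken:
            return key


def generate_raw_calls(
    patient: PatientRecord,
    panel_sites: list[_panel.HotspotSite] | None = None,
    config: CohortConfig | None = None,
) -> tuple[dict[str, list[VariantCall]], list[VariantCall]]:
    """Raw caller output per timepoint plus the matched PBL call set.

    Somatic alt counts are binomial at the configured depth around the
    ground-truth VAF. Injected contaminants are tagged with their class:
    germline polymorphisms (VAF ~ 0.5, present in plasma and PBL at
    reserved whitelist sites), strand-skewed artifacts (>= 90% of alt
    reads on one strand), and sub-threshold noise (VAF < 0.5%,
    off-panel). Zero requested contaminants leaves the raw set equal to
    the binomially sampled somatic truth.
    """
    config = config or CohortConfig()
    panel_sites = panel_sites if panel_sites is not None else _panel.default_whitelist()
    if not panel_sites:
        raise ValueError("panel_sites must be non-empty")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    site_by_key = {s.key: s for s in panel_sites}
    rng = _rng(config.seed, stream=1, index=patient.index)
    depth = int(config.depth)

    # patient-constant germline loci and heterozygous fractions
    germ_pool = [s for s in panel_sites if s in _panel.GERMLINE_RESERVED_SITES] or [
        s for s in _panel.GERMLINE_RESERVED_SITES
    ]
    n_germ = min(config.n_germline_contaminants, len(germ_pool))
    germ_idx = rng.choice(len(germ_pool), size=n_germ, replace=False) if n_germ else []
    germ_sites = [germ_pool[int(j)] for j in germ_idx]
    germ_fractions = [float(rng.normal(0.5, 0.02)) for _ in germ_sites]

    artifact_pool = [s for s in panel_sites if s in _panel.ARTIFACT_RESERVED_SITES] or [
        s for s in _panel.ARTIFACT_RESERVED_SITES
    ]

    calls_by_tp: dict[str, list[VariantCall]] = {}
    taken = set(site_by_key)
    for tp in patient.timepoints_present:
        calls: list[VariantCall] = []
        for key, vaf in patient.truth_mutations.get(tp, {}).items():
            site = site_by_key.get(key)
            call = _binom_call(
                rng,
                key,
                depth,
                vaf,
                config.error_rate,
                gene=site.gene if site else "",
                aa_change=site.aa_change if site else "",
                truth_class=SOMATIC,
            )
            if call is not None:
                calls.append(call)
        for site, fraction in zip(germ_sites, germ_fractions):
            call = _binom_call(
                rng, site.key, depth, fraction, config.error_rate,
                gene=site.gene, aa_change=site.aa_change, truth_class=GERMLINE,
            )
            if call is not None:
                calls.append(call)
        n_art = min(config.n_artifact_contaminants, len(artifact_pool))
        if n_art:
            for j in rng.choice(len(artifact_pool), size=n_art, replace=False):
                site = artifact_pool[int(j)]
                call = _binom_call(
                    rng, site.key, depth, float(rng.uniform(0.01, 0.05)),
                    config.error_rate,
                    gene=site.gene, aa_change=site.aa_change, truth_class=ARTIFACT,
                    minor_strand_fraction=float(rng.uniform(0.0, 0.05)),
                )
                if call is not None:
                    calls.append(call)
        for _ in range(config.n_noise_contaminants):
            key = _random_offpanel_site(rng, taken)
            call = _binom_call(
                rng, key, depth, float(rng.uniform(0.0005, 0.003)),
                config.error_rate, truth_class=NOISE,
            )
            if call is not None:
                calls.append(call)
        calls_by_tp[tp] = calls

    pbl_calls: list[VariantCall] = []
    for site, fraction in zip(germ_sites, germ_fractions):
        call = _binom_call(
            rng, site.key, depth, fraction, config.error_rate,
            gene=site.gene, aa_change=site.aa_change, truth_class=GERMLINE,
        )
        if call is not None:
            pbl_calls.append(call)
    return calls_by_tp, pbl_calls


def generate_full_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[_panel.HotspotSite]]:
    """Cohort with raw calls attached, plus the hotspot whitelist."""
    cohort = generate_cohort(config)
    whitelist = _panel.default_whitelist()
    for patient in cohort:
        calls_by_tp, pbl = generate_raw_calls(patient, whitelist, config)
        patient.pbl_calls = pbl
        for tp, calls in calls_by_tp.items():
            patient.samples[tp].raw_calls = calls
    return cohort, whitelist


# ---------------------------------------------------------------------------
# reference standards


@dataclass
class ReferenceStandardSet:
    """Replicate VAF measurements of mixed mutant-fraction standards."""

    nominal_fractions: tuple[float, ...]
    replicates_per_fraction: int
    depth: int
    measured: dict[float, list[float]]

    def __post_init__(self) -> None:
        for fraction, values in self.measured.items():
            if len(values) != self.replicates_per_fraction:
                raise ValueError(
                    f"fraction {fraction}: expected {self.replicates_per_fraction} "
                    f"replicates, got {len(values)}"
                )
            if any(v < 0 for v in values):
                raise ValueError(f"fraction {fraction}: measured VAFs must be >= 0")

    @property
    def n_measurements(self) -> int:
        return len(self.nominal_fractions) * self.replicates_per_fraction


def generate_reference_standards(
    nominal_fractions: tuple[float, ...] = (0.0, 0.005, 0.01),
    replicates: int = 10,
    depth: int = 10_000,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReferenceStandardSet:
    """Simulate replicate sequencing of mutant-fraction reference standards.

    Negative controls (fraction 0) measure background error only;
    positive standards measure the nominal fraction plus background.
    """
    fractions = tuple(float(f) for f in nominal_fractions)
    if list(fractions) != sorted(fractions):
        raise ValueError("nominal_fractions must be sorted ascending")
    if not fractions or fractions[0] != 0.0:
        raise ValueError("nominal_fractions must start with the zero (negative) level")
    if replicates < 2:
        raise ValueError("at least 2 replicates per fraction are required")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed, stream=3)
    measured: dict[float, list[float]] = {}
    for fraction in fractions:
        p = fraction + (1.0 - fraction) * error_rate
        alts = rng.binomial(depth, p, size=replicates)
        measured[fraction] = [int(a) / depth for a in alts]
    return ReferenceStandardSet(
        nominal_fractions=fractions,
        replicates_per_fraction=replicates,
        depth=depth,
        measured=measured,
    )


# ---------------------------------------------------------------------------
# standalone tagged call sets for filter validation


@dataclass
class TaggedCallSample:
    """A single synthetic sample with ground-truth-labelled calls."""

    plasma_calls: list[VariantCall]
    pbl_calls: list[VariantCall]
    whitelist: list[tuple]
    avg_depth: float


def generate_tagged_calls(
    n_somatic: int = 350,
    n_germline: int = 50,
    n_artifact: int = 50,
    n_noise: int = 50,
    depth: int = 12_000,
    error_rate: float = 0.001,
    seed: int = 0,
) -> TaggedCallSample:
    """One large call set with known class labels for filter-recall tests.

    Somatic truth VAFs are drawn uniform on [1%, 20%] (comfortably above
    the 0.5% gate) at synthetic whitelist loci; germline contaminants sit
    near 50% and are mirrored in the PBL set; artifacts carry >= 95% of
    alt reads on one strand; noise calls are sub-threshold and off the
    whitelist.
    """
    rng = _rng(seed, stream=4)
    whitelist: list[tuple] = []
    plasma: list[VariantCall] = []
    pbl: list[VariantCall] = []
    pos = 1_000_000

    def next_site() -> tuple:
        nonlocal pos
        pos += 1000
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
        return ("chr1", pos, ref, alt)

    for _ in range(n_somatic):
        key = next_site()
        whitelist.append(key)
        call = _binom_call(rng, key, depth, float(rng.uniform(0.01, 0.2)), error_rate,
                           truth_class=SOMATIC)
        if call is not None:
            plasma.append(call)
    for _ in range(n_germline):
        key = next_site()
        whitelist.append(key)
        fraction = float(rng.normal(0.5, 0.02))
        call = _binom_call(rng, key, depth, fraction, error_rate, truth_class=GERMLINE)
        if call is not None:
            plasma.append(call)
        pbl_call = _binom_call(rng, key, depth, fraction, error_rate, truth_class=GERMLINE)
        if pbl_call is not None:
            pbl.append(pbl_call)
    for _ in range(n_artifact):
        key = next_site()
        whitelist.append(key)
        call = _binom_call(
            rng, key, depth, float(rng.uniform(0.01, 0.05)), error_rate,
            truth_class=ARTIFACT, minor_strand_fraction=float(rng.uniform(0.0, 0.05)),
        )
        if call is not None:
            plasma.append(call)
    taken = set(whitelist)
    for _ in range(n_noise):
        key = _random_offpanel_site(rng, taken)
        taken.add(key)
        call = _binom_call(rng, key, depth, float(rng.uniform(0.0005, 0.003)), error_rate,
                           truth_class=NOISE)
        if call is not None:
            plasma.append(call)
    return TaggedCallSample(
        plasma_calls=plasma, pbl_calls=pbl, whitelist=whitelist, avg_depth=float(depth)
    )
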