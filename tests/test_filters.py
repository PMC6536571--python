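"""Four-step somatic filtering: thresholds, strand bias, hotspots, germline."""

import math

import numpy as np
import pytest
from scipy import stats

from ctdnaflow.calls import ARTIFACT, GERMLINE, NOISE, SOMATIC, VariantCall
from ctdnaflow.filters import (
    STEP_GERMLINE,
    STEP_HOTSPOT,
    STEP_PRIMARY,
    STEP_STRAND,
    FilterThresholds,
    call_pvalue,
    filter_pipeline,
    germline_filter,
    hotspot_filter,
    primary_filter,
    read_length_qc,
    strand_bias_filter,
)
from ctdnaflow.synthetic import generate_tagged_calls

from .conftest import make_call


class TestCallPvalue:
    def test_zero_alt_reads_gives_one(self):
        assert call_pvalue(0, 10_000, 0.001) == 1.0

    def test_all_alt_reads_is_error_rate_power(self):
        # P(X >= 10 | n=10, p) = p^10
        assert call_pvalue(10, 10, 0.001) == pytest.approx(1e-30, rel=1e-9)

    def test_matches_direct_pmf_summation(self):
        # independent oracle: sum the binomial pmf over k = 25..10,000
        expected = sum(
            stats.binom.pmf(k, 10_000, 0.001) for k in range(25, 200)
        )  # pmf beyond k=200 is below float underflow here
        assert call_pvalue(25, 10_000, 0.001) == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            call_pvalue(1, 0, 0.001)
        with pytest.raises(ValueError):
            call_pvalue(5, 10, 0.0)


class TestPrimaryFilter:
    def test_call_above_all_thresholds_kept(self):
        call = make_call(vaf=0.0052, depth=10_000, p_value=1e-6)
        assert call.alt_count == 52
        assert primary_filter([call], sample_avg_depth=10_001) == [call]

    @pytest.mark.parametrize(
        "vaf, depth, avg_depth, p, kept",
        [
            (0.005, 10_000, 10_001, 1e-6, False),  # VAF boundary: strict >
            (0.0052, 10_000, 10_000, 1e-6, False),  # avg depth boundary
            (0.0011, 10_000, 10_001, 1e-6, False),  # 11 alt reads > 10 but vaf fails
            (0.0052, 10_000, 10_001, 0.01, False),  # p boundary: strict <
            (0.02, 10_000, 10_001, 1e-6, True),
        ],
    )
    def test_strict_threshold_boundaries(self, vaf, depth, avg_depth, p, kept):
        call = make_call(vaf=vaf, depth=depth, p_value=p)
        assert bool(primary_filter([call], avg_depth)) is kept

    def test_coverage_threshold_is_strict(self):
        t = FilterThresholds()
        # exactly 10 alt reads at high VAF in low depth: coverage must be > 10
        call = VariantCall("chr1", 1, "A", "T", depth=1000, alt_count=10,
                           alt_fwd=5, alt_rev=5, ref_fwd=495, ref_rev=495,
                           p_value=1e-9)
        assert primary_filter([call], 20_000, t) == []

    def test_matches_bruteforce_predicate_on_random_calls(self, rng):
        t = FilterThresholds()
        calls = []
        for _ in range(100):
            depth = int(rng.integers(1000, 20_000))
            alt = int(rng.integers(0, depth // 3))
            calls.append(
                VariantCall(
                    "chr1", int(rng.integers(1, 10**6)), "A", "T",
                    depth=depth, alt_count=alt,
                    alt_fwd=alt // 2, alt_rev=alt - alt // 2,
                    ref_fwd=(depth - alt) // 2,
                    ref_rev=(depth - alt) - (depth - alt) // 2,
                    p_value=float(rng.uniform(0, 0.05)),
                )
            )
        avg_depth = 10_500.0
        expected = [
            c
            for c in calls
            if avg_depth > t.min_avg_depth
            and c.alt_count > t.min_variant_coverage
            and c.vaf > t.min_vaf
            and c.p_value < t.max_p
        ]
        result = primary_filter(calls, avg_depth, t)
        assert result == expected
        # idempotent and order preserving, input untouched
        assert primary_filter(result, avg_depth, t) == result
        assert len(calls) == 100


class TestStrandBias:
    def test_balanced_call_kept(self):
        call = VariantCall("chr1", 1, "A", "T", depth=10_000, alt_count=100,
                           alt_fwd=50, alt_rev=50, ref_fwd=4950, ref_rev=4950)
        keep, reason = strand_bias_filter(call)
        assert keep and reason is None

    def test_fully_skewed_call_dropped(self):
        call = VariantCall("chr1", 1, "A", "T", depth=10_000, alt_count=100,
                           alt_fwd=100, alt_rev=0, ref_fwd=4900, ref_rev=5000)
        # oracle: Fisher p by direct hypergeometric enumeration
        table = np.array([[100, 0], [4900, 5000]])
        p_obs = stats.hypergeom.pmf(100, 10_000, 100, 5000)
        p_total = sum(
            stats.hypergeom.pmf(k, 10_000, 100, 5000)
            for k in range(101)
            if stats.hypergeom.pmf(k, 10_000, 100, 5000) <= p_obs * (1 + 1e-9)
        )
        assert p_total < 1e-3
        keep, reason = strand_bias_filter(call)
        assert not keep and "strand bias" in reason

    def test_minor_strand_fraction_guard_keeps_mild_imbalance(self):
        call = VariantCall("chr1", 1, "A", "T", depth=100, alt_count=12,
                           alt_fwd=7, alt_rev=5, ref_fwd=40, ref_rev=48)
        keep, _ = strand_bias_filter(call)
        assert keep  # minor fraction 5/12 >= 0.1 regardless of p

    def test_zero_alt_reads_rejected(self):
        call = VariantCall("chr1", 1, "A", "T", depth=100, alt_count=0,
                           alt_fwd=0, alt_rev=0, ref_fwd=50, ref_rev=50)
        with pytest.raises(ValueError):
            strand_bias_filter(call)


class TestHotspotFilter:
    def test_whitelisted_kept_unlisted_dropped(self):
        call = make_call(pos=123)
        other = make_call(pos=456)
        kept = hotspot_filter([call, other], [("chr1", 123, "A", "T")])
        assert kept == [call]

    def test_equals_set_intersection_oracle(self, rng):
        calls = [make_call(pos=int(p)) for p in rng.choice(1000, 50, replace=False)]
        whitelist = [("chr1", int(p), "A", "T") for p in rng.choice(1000, 20, replace=False)]
        keys = set(whitelist)
        expected = [c for c in calls if c.key in keys]
        assert hotspot_filter(calls, whitelist) == expected

    def test_empty_whitelist_warns_and_empties(self):
        with pytest.warns(UserWarning, match="whitelist is empty"):
            assert hotspot_filter([make_call()], []) == []


class TestGermlineFilter:
    def test_heterozygous_pbl_match_removed(self):
        plasma = make_call(vaf=0.079, pos=500, gene="KRAS", aa_change="G12D")
        pbl = make_call(vaf=0.49, pos=500)
        somatic, germline = germline_filter([plasma], [pbl])
        assert somatic == [] and germline == [plasma]

    def test_plasma_only_variant_kept(self):
        plasma = make_call(vaf=0.079, pos=500)
        pbl = make_call(vaf=0.49, pos=999)
        somatic, germline = germline_filter([plasma], [pbl])
        assert somatic == [plasma] and germline == []

    def test_low_vaf_pbl_noise_does_not_trigger_removal(self):
        plasma = make_call(vaf=0.079, pos=500)
        pbl = make_call(vaf=0.005, pos=500)
        somatic, _ = germline_filter([plasma], [pbl])
        assert somatic == [plasma]


class TestFilterPipeline:
    def test_clean_sample_passes_whitelist_intersection(self):
        calls = [make_call(vaf=0.05, pos=100), make_call(vaf=0.03, pos=200)]
        whitelist = [("chr1", 100, "A", "T")]
        res = filter_pipeline(calls, [], 12_000, whitelist)
        assert res.passed == [calls[0]]
        assert [e.step for e in res.audit] == [STEP_HOTSPOT]

    def test_contaminants_removed_at_designated_steps(self):
        sample = generate_tagged_calls(
            n_somatic=20, n_germline=5, n_artifact=5, n_noise=5, seed=11
        )
        res = filter_pipeline(
            sample.plasma_calls, sample.pbl_calls, sample.avg_depth, sample.whitelist
        )
        step_of_class = {
            (e.call.truth_class, e.step) for e in res.audit
        }
        assert step_of_class <= {
            (NOISE, STEP_PRIMARY),
            (ARTIFACT, STEP_STRAND),
            (GERMLINE, STEP_GERMLINE),
        }
        assert all(c.truth_class == SOMATIC for c in res.passed)

    def test_germline_call_failing_vaf_logged_at_primary_step(self):
        # order contract: a sub-threshold germline call dies at step 1
        germ = make_call(vaf=0.004, pos=700, truth_class=GERMLINE)
        pbl = make_call(vaf=0.5, pos=700)
        res = filter_pipeline([germ], [pbl], 12_000, [germ.key])
        assert res.passed == []
        assert res.audit[0].step == STEP_PRIMARY

    def test_output_subset_and_count_conservation(self, default_cohort):
        cohort, whitelist = default_cohort
        patient = cohort[0]
        sample = patient.samples["C0"]
        res = filter_pipeline(
            sample.raw_calls, patient.pbl_calls, sample.avg_depth, whitelist
        )
        raw_keys = {c.key for c in sample.raw_calls}
        assert all(c.key in raw_keys for c in res.passed)
        assert len(res.passed) + res.n_dropped == len(sample.raw_calls)

    def test_pipeline_idempotent_on_its_own_output(self, default_cohort):
        cohort, whitelist = default_cohort
        patient = cohort[1]
        sample = patient.samples["C0"]
        first = filter_pipeline(
            sample.raw_calls, patient.pbl_calls, sample.avg_depth, whitelist
        )
        second = filter_pipeline(
            first.passed, patient.pbl_calls, sample.avg_depth, whitelist
        )
        assert second.passed == first.passed
        assert second.n_dropped == 0


class TestReadLengthQC:
    def test_bounds_inclusive(self):
        qc = read_length_qc([59, 60, 106, 160, 161])
        assert qc.mask.tolist() == [False, True, True, True, False]
        assert qc.n_kept == 3 and qc.kept_fraction == pytest.approx(0.6)

    def test_empty_input_is_zero_over_zero(self):
        qc = read_length_qc([])
        assert qc.n_total == 0 and math.isnan(qc.kept_fraction)

    def test_uniform_in_range_keeps_everything(self):
        qc = read_length_qc([100] * 7)
        assert qc.kept_fraction == 1.0
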