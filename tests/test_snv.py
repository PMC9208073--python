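"""Somatic filter chain: every rule branch, rescue, TMB arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccrcc_wes.io_formats import (
    CaptureRegion,
    CoverageRow,
    RunConfig,
    Segment,
)
from ccrcc_wes.snv import (
    compute_tmb,
    correct_vaf,
    filter_variants,
    infer_multiplicity,
    local_copy_number,
)
from ccrcc_wes.synthetic import SimConfig, simulate_cohort


class TestCorrectVaf:
    @pytest.mark.parametrize("vaf,purity,cn,expected", [
        (0.25, 0.5, 2, 0.5),
        (0.3, 1.0, 2, 0.3),    # identity at full purity
        (0.6, 0.5, 2, 1.0),    # capped
        (0.111111, 0.2, 1, 0.999999),  # LOH at low purity -> ~1
    ])
    def test_closed_forms(self, vaf, purity, cn, expected):
        assert correct_vaf(vaf, purity, cn) == pytest.approx(expected,
                                                             abs=1e-4)

    def test_zero_local_cn_is_inconsistent_input(self):
        with pytest.raises(ValueError, match="copy number"):
            correct_vaf(0.2, 0.5, 0)

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            correct_vaf(0.2, 0.0, 2)

    def test_corrected_never_below_raw_for_diploid(self, variant_factory):
        for purity in (0.2, 0.5, 0.9, 1.0):
            assert correct_vaf(0.1, purity, 2) >= 0.1


class TestLocalCn:
    def test_unsegmented_territory_is_diploid(self, variant_factory):
        assert local_copy_number(variant_factory(), None) == 2
        assert local_copy_number(variant_factory(), []) == 2

    def test_cn_from_corrected_segment_mean(self, variant_factory):
        call = variant_factory(chrom="3", pos=500)
        seg_loss = Segment("3", 0, 1000, 5, -1.0)
        assert local_copy_number(call, [seg_loss]) == 1
        seg_amp = Segment("3", 0, 1000, 5, 1.0)
        assert local_copy_number(call, [seg_amp]) == 4

    def test_deep_deletion_clamps_to_one(self, variant_factory):
        call = variant_factory(chrom="3", pos=500)
        assert local_copy_number(call, [Segment("3", 0, 1000, 5, -6.0)]) \
            == 1

    def test_loh_promotes_multiplicity(self, variant_factory):
        # raw VAF far above the multiplicity-1 ceiling at CN 2
        call = variant_factory(tumor_ref_reads=20, tumor_alt_reads=80)
        assert infer_multiplicity(call, 0.5, 2) == 2
        balanced = variant_factory(tumor_ref_reads=75, tumor_alt_reads=25)
        assert infer_multiplicity(balanced, 0.5, 2) == 1


class TestFilterChain:
    def test_clean_nonsynonymous_variant_kept(self, run_config,
                                              variant_factory):
        call = variant_factory(tumor_ref_reads=8, tumor_alt_reads=4)
        filter_variants([call], 1.0, None, run_config)
        assert call.filter_status == "keep"
        assert call.vaf_corrected == pytest.approx(1 / 3)

    def test_variant_in_normal_dropped_first(self, run_config,
                                             variant_factory):
        call = variant_factory(normal_ref_reads=55, normal_alt_reads=45,
                               effect="synonymous")
        filter_variants([call], 1.0, None, run_config)
        assert call.filter_status == "drop_in_normal"  # precedence

    def test_synonymous_dropped(self, run_config, variant_factory):
        call = variant_factory(effect="synonymous")
        filter_variants([call], 1.0, None, run_config)
        assert call.filter_status == "drop_synonymous"

    @pytest.mark.parametrize("depth,status", [
        (10, "keep"), (9, "drop_low_reads"),
    ])
    def test_ten_read_rule_boundary(self, run_config, variant_factory,
                                    depth, status):
        call = variant_factory(tumor_ref_reads=depth - 4,
                               tumor_alt_reads=4)
        filter_variants([call], 1.0, None, run_config)
        assert call.filter_status == status

    def test_low_corrected_vaf_dropped_without_cosmic(self, run_config,
                                                      variant_factory):
        # corrected VAF 0.08 and only 3 COSMIC reports: dropped
        call = variant_factory(tumor_ref_reads=92, tumor_alt_reads=8,
                               cosmic_count=3)
        filter_variants([call], 1.0, None, run_config)
        assert call.filter_status == "drop_low_corrected_vaf"
        assert not call.rescued_by_cosmic

    @pytest.mark.parametrize("cosmic,normal_alt,rescued", [
        (15, 0, True),    # >=10 reports, VAF 7% > 5%, normal 0 < 1%
        (9, 0, False),    # below the report threshold
        (15, 2, False),   # normal VAF 2% >= 1%
    ])
    def test_cosmic_rescue_boundaries(self, run_config, variant_factory,
                                      cosmic, normal_alt, rescued):
        call = variant_factory(tumor_ref_reads=93, tumor_alt_reads=7,
                               normal_ref_reads=100 - normal_alt,
                               normal_alt_reads=normal_alt,
                               cosmic_count=cosmic)
        filter_variants([call], 1.0, None, run_config)
        assert call.rescued_by_cosmic is rescued
        assert call.kept is rescued

    def test_rescue_requires_tumor_vaf_above_5pct(self, run_config,
                                                  variant_factory):
        call = variant_factory(tumor_ref_reads=96, tumor_alt_reads=4,
                               cosmic_count=50)
        filter_variants([call], 1.0, None, run_config)
        assert call.filter_status == "drop_low_corrected_vaf"

    def test_conservation_and_order_independence(self, run_config,
                                                 variant_factory):
        rng = np.random.default_rng(0)
        calls = [variant_factory(pos=100 + i,
                                 tumor_ref_reads=int(rng.integers(0, 120)),
                                 tumor_alt_reads=int(rng.integers(0, 40)),
                                 effect=["missense", "synonymous"][i % 2])
                 for i in range(30)]
        filter_variants(calls, 0.6, None, run_config)
        status_by_key = {c.key: c.filter_status for c in calls}
        shuffled = calls[::-1]
        filter_variants(shuffled, 0.6, None, run_config)
        assert {c.key: c.filter_status for c in shuffled} == status_by_key
        assert len(calls) == 30  # every record still present, once

    @given(st.integers(0, 40), st.integers(5, 120))
    @settings(derandomize=True, max_examples=60)
    def test_raising_vaf_threshold_never_keeps_more(self, alt, ref):
        from tests.conftest import make_variant
        call = make_variant(tumor_ref_reads=ref, tumor_alt_reads=alt)
        kept = []
        for thr in (0.05, 0.10, 0.20, 0.40):
            config = RunConfig(min_corrected_vaf=thr)
            filter_variants([call], 0.7, None, config)
            kept.append(call.kept)
        # once dropped at some threshold, higher thresholds keep dropping
        assert kept == sorted(kept, reverse=True)


class TestTmb:
    def _coverage(self, n=40, length=1000, reads=500):
        return [CoverageRow(CaptureRegion("1", i * 10_000,
                                          i * 10_000 + length), reads,
                            reads) for i in range(n)]

    def test_tmb_arithmetic(self, run_config, variant_factory):
        # 85 kept nonsynonymous over 34 Mb -> 2.5 mutations/Mb
        calls = [variant_factory(pos=100 + i) for i in range(85)]
        coverage = self._coverage(n=34, length=10**6)
        result = compute_tmb(calls, coverage, run_config)
        assert result.covered_mb == pytest.approx(34.0)
        assert result.tmb == pytest.approx(2.5)
        assert result.indel_fraction == 0.0

    def test_zero_kept_variants(self, run_config, variant_factory):
        call = variant_factory(effect="synonymous",
                               filter_status="drop_synonymous")
        result = compute_tmb([call], self._coverage(), run_config)
        assert result.tmb == 0.0

    def test_indel_fraction_counts_effect_classes(self, run_config,
                                                  variant_factory):
        calls = [variant_factory(pos=1, effect="missense"),
                 variant_factory(pos=2, effect="frameshift_indel",
                                 ref="A", alt="AT"),
                 variant_factory(pos=3, effect="inframe_indel",
                                 ref="A", alt="ATTT"),
                 variant_factory(pos=4, effect="nonsense")]
        result = compute_tmb(calls, self._coverage(), run_config)
        assert result.indel_fraction == pytest.approx(0.5)

    def test_low_coverage_regions_not_counted(self, run_config,
                                              variant_factory):
        coverage = self._coverage(n=10, length=10**6, reads=500) + \
            [CoverageRow(CaptureRegion("2", 0, 10**6), 50, 50)]
        result = compute_tmb([variant_factory()], coverage, run_config)
        assert result.covered_mb == pytest.approx(10.0)


class TestPlantedSensitivity:
    def test_clonal_nonsynonymous_sensitivity_above_95pct(self):
        """At purity >= 0.4 and depth 100, planted clonal nonsynonymous
        SNVs must survive the filter chain >95% of the time."""
        config = SimConfig(n_patients=10, n_multi_sample_patients=0,
                           purity_range=(0.4, 0.9), rng_seed=77)
        run_config = RunConfig()
        truth, obs = simulate_cohort(config)
        planted = kept = 0
        for pid, tp in truth.patients.items():
            sid = tp.sample_ids[0]
            calls = obs["tables"][sid]["variants"]
            filter_variants(calls, tp.purity[sid], None, run_config)
            status = {c.key: c.kept for c in calls}
            for snv in tp.snvs:
                if (snv.effect != "synonymous" and not snv.germline_leak
                        and snv.clonality >= 1.0):
                    planted += 1
                    kept += status[snv.key]
        assert planted > 300
        assert kept / planted > 0.95
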