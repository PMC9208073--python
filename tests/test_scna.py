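"""Copy-number stage: filtering, log2 correction, CBS, calls, burden."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccrcc_wes.io_formats import (
    CaptureRegion,
    CoverageRow,
    Cytoband,
    RunConfig,
    Segment,
)
from ccrcc_wes.scna import (
    Log2Profile,
    annotate_cytobands,
    classify_segment,
    cna_burden,
    cohort_recurrence,
    compute_log2,
    correct_segment_means,
    filter_regions,
    needs_ploidy_review,
    segment_cbs,
)


def region(chrom="1", i=0, length=1000):
    return CaptureRegion(chrom, i * 10_000, i * 10_000 + length)


def cov(t, n, chrom="1", i=0):
    return CoverageRow(region(chrom, i), t, n)


def profile(values, chrom="1"):
    regions = [region(chrom, i) for i in range(len(values))]
    v = np.asarray(values, dtype=float)
    return Log2Profile(regions, v, v)


class TestRegionFilter:
    @pytest.mark.parametrize("t,n,kept", [
        (150, 40, True),    # one side well covered: retained (AND rule)
        (40, 40, False),    # both below: excluded
        (100, 100, True),   # boundary: "< 100" is strict
        (99, 100, True),
        (99, 99, False),
    ])
    def test_and_rule_boundaries(self, t, n, kept):
        rows = [cov(t, n), cov(500, 500, i=1)]
        result = filter_regions(rows, min_cov=100, mode="and")
        assert (rows[0] in result) == kept

    def test_or_rule_requires_both(self):
        assert filter_regions([cov(150, 40), cov(150, 150, i=1)],
                              mode="or") == [cov(150, 150, i=1)]

    def test_everything_excluded_is_error(self):
        with pytest.raises(ValueError, match="coverage filter"):
            filter_regions([cov(10, 10)], min_cov=100)


class TestLog2:
    def test_equal_normalized_counts_give_zero(self):
        rows = [cov(100, 200, i=i) for i in range(4)]
        prof = compute_log2(rows, purity=1.0)
        assert np.allclose(prof.log2_raw, 0.0)
        assert np.allclose(prof.log2_corrected, prof.log2_raw)

    @pytest.mark.parametrize("r,purity,expected", [
        (0.75, 0.5, -1.0),  # one-copy loss restored to deletion scale
        (1.5, 0.5, 1.0),
        (0.8, 1.0, np.log2(0.8)),  # identity at purity 1
    ])
    def test_segment_mean_correction_closed_form(self, r, purity,
                                                 expected):
        seg = Segment("1", 0, 1000, 3, float(np.log2(r)))
        correct_segment_means([seg], purity)
        assert seg.seg_mean == pytest.approx(expected)

    def test_zero_normal_regions_dropped(self):
        rows = [cov(100, 0), cov(100, 100, i=1), cov(90, 110, i=2)]
        prof = compute_log2(rows, purity=1.0)
        assert len(prof.regions) == 2


class TestCbs:
    def test_constant_profile_single_segment(self):
        rng = np.random.default_rng(0)
        segs = segment_cbs(profile(np.zeros(200)), rng=rng)
        assert len(segs) == 1
        assert segs[0].seg_mean == pytest.approx(0.0)
        assert segs[0].n_regions == 200

    def test_step_profile_recovered(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.2, 100),
                            rng.normal(-1, 0.2, 100)])
        segs = segment_cbs(profile(x), rng=np.random.default_rng(2))
        assert len(segs) == 2
        assert abs(segs[0].n_regions - 100) <= 3
        assert segs[0].seg_mean == pytest.approx(0.0, abs=0.1)
        assert segs[1].seg_mean == pytest.approx(-1.0, abs=0.1)

    def test_first_breakpoint_matches_exhaustive_oracle(self):
        """Independent brute-force max arc statistic must pick the same
        first split as the CBS search on a clean step."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.2, 60),
                            rng.normal(-1, 0.2, 40)])

        def oracle_split(x, min_width=3):
            n = len(x)
            s = np.std(x, ddof=1)
            best, arg = -1.0, None
            for i in range(n + 1):
                for j in range(i + min_width, n + 1):
                    k = j - i
                    if k > n - min_width:
                        continue
                    arc = x[i:j]
                    rest = np.concatenate([x[:i], x[j:]])
                    t = abs(arc.mean() - rest.mean()) / (
                        s * np.sqrt(1 / k + 1 / (n - k)))
                    if t > best:
                        best, arg = t, (i, j)
            return arg

        i, j = oracle_split(x)
        segs = segment_cbs(profile(x), rng=np.random.default_rng(4))
        bounds = np.cumsum([s.n_regions for s in segs])[:-1]
        assert set(bounds) <= {i, j}
        assert len(bounds) >= 1 and bounds[0] in (i, j)

    def test_alpha_zero_limit_returns_one_segment(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.2, 50),
                            rng.normal(-1, 0.2, 50)])
        segs = segment_cbs(profile(x), alpha=1e-9, nperm=200, rng=rng)
        assert len(segs) == 1

    def test_short_chromosome_single_segment(self):
        segs = segment_cbs(profile([0.1, 0.2, -0.1, 0.0]), min_width=3,
                           rng=np.random.default_rng(0))
        assert len(segs) == 1

    def test_region_conservation_and_mean_identity(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.25, 70),
                            rng.normal(0.8, 0.25, 50),
                            rng.normal(-1.2, 0.25, 60)])
        segs = segment_cbs(profile(x), rng=np.random.default_rng(7))
        assert sum(s.n_regions for s in segs) == len(x)
        pos = 0
        for s in segs:
            member = x[pos:pos + s.n_regions]
            assert s.seg_mean == pytest.approx(member.mean(), abs=1e-9)
            pos += s.n_regions

    def test_multi_chromosome_profiles_segment_independently(self):
        rng = np.random.default_rng(8)
        regions = [region("1", i) for i in range(50)] + \
                  [region("2", i) for i in range(50)]
        v = np.concatenate([rng.normal(0, 0.2, 50),
                            rng.normal(-1, 0.2, 50)])
        prof = Log2Profile(regions, v, v)
        segs = segment_cbs(prof, rng=rng)
        assert [s.chrom for s in segs] == ["1", "2"]


class TestClassification:
    @pytest.mark.parametrize("mean,call", [
        (1.2, "amplified"),
        (1.0, "gain"),
        (0.7, "gain"),
        (0.5, "neutral"),
        (0.0, "neutral"),
        (-0.5, "neutral"),
        (-0.7, "loss"),
        (-1.0, "loss"),
        (-1.01, "deletion"),
    ])
    def test_five_class_boundaries(self, mean, call, run_config):
        assert classify_segment(mean, run_config) == call


class TestAnnotationAndBurden:
    BANDS = [Cytoband("3", 0, 10_000_000, "3p25"),
             Cytoband("3", 10_000_000, 50_000_000, "3p"),
             Cytoband("3", 50_000_000, 100_000_000, "3q")]

    def test_segment_lists_overlapped_bands(self):
        seg = Segment("3", 5_000_000, 20_000_000, 10, -0.8)
        annotate_cytobands([seg], self.BANDS)
        assert seg.cytobands == ["3p25", "3p"]

    def test_review_flag_for_genome_wide_shift(self):
        segs = [Segment("1", 0, 10**8, 50, -0.6, call="loss",
                        region_bp=10**6),
                Segment("2", 0, 10**8, 50, -0.7, call="loss",
                        region_bp=10**6)]
        assert needs_ploidy_review(segs)

    def test_no_flag_for_focal_events(self):
        segs = [Segment("1", 0, 10**8, 50, 0.0, call="neutral",
                        region_bp=10**6),
                Segment("2", 0, 10**6, 3, -1.2, call="deletion",
                        region_bp=10**4)]
        assert not needs_ploidy_review(segs)

    def test_burden_excludes_sex_chromosomes_by_default(self):
        segs = [Segment("1", 0, 100, 1, 0.0, call="neutral",
                        region_bp=100),
                Segment("X", 0, 100, 1, -0.8, call="loss",
                        region_bp=100)]
        assert cna_burden(segs).fraction_altered == 0.0
        assert cna_burden(segs, include_sex=True).fraction_altered == 0.5

    def test_burden_invariant_to_segment_order(self):
        segs = [Segment("1", 0, 100, 1, -0.8, call="loss", region_bp=70),
                Segment("2", 0, 100, 1, 0.0, call="neutral",
                        region_bp=30)]
        assert cna_burden(segs).fraction_altered == \
            cna_burden(segs[::-1]).fraction_altered


class TestRecurrence:
    BANDS = [Cytoband("9", 0, 10, "9p21"), Cytoband("9", 10, 100, "9p")]

    def _loss(self):
        return Segment("9", 0, 8, 4, -0.8, call="loss")

    def test_patient_with_multiple_lossy_samples_counts_once(self):
        segs = {"P1": [[self._loss()], [self._loss()], [self._loss()]]}
        table = cohort_recurrence(segs, self.BANDS).set_index("cytoband")
        assert table.loc["9p21", "loss_patients"] == 1

    def test_two_of_three_patients(self):
        segs = {"P1": [[self._loss()]], "P2": [[self._loss()]],
                "P3": [[Segment("9", 0, 8, 4, 0.0, call="neutral")]]}
        table = cohort_recurrence(segs, self.BANDS).set_index("cytoband")
        assert table.loc["9p21", "loss_patients"] == 2
        assert table.loc["9p21", "gain_patients"] == 0


@given(st.floats(-3, 3))
@settings(derandomize=True, max_examples=60)
def test_classification_consistent_with_thresholds(mean):
    """Each call class maps back onto its defining interval."""
    config = RunConfig()
    call = classify_segment(mean, config)
    if call == "amplified":
        assert mean > config.log2_amp
    elif call == "gain":
        assert config.log2_gain < mean <= config.log2_amp
    elif call == "neutral":
        assert config.log2_loss <= mean <= config.log2_gain
    elif call == "loss":
        assert config.log2_del <= mean < config.log2_loss
    else:
        assert mean < config.log2_del
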