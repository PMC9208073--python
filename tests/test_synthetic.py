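"""Generator closed forms, determinism and cross-table consistency."""

import numpy as np
import pytest

from ccrcc_wes.synthetic import (
    SimConfig,
    emit_cohort,
    expected_coverage_ratio,
    expected_het_fraction,
    expected_vaf,
    simulate_cohort,
    simulate_coverage,
    simulate_het_snps,
    simulate_patient_tree,
    simulate_variant_reads,
)


class TestClosedForms:
    @pytest.mark.parametrize("clonality,purity,cn,mult,expected", [
        (1.0, 1.0, 2, 1, 0.5),    # pure diploid het
        (1.0, 0.4, 2, 1, 0.2),
        (0.5, 0.5, 2, 1, 0.125),
    ])
    def test_expected_vaf(self, clonality, purity, cn, mult, expected):
        assert expected_vaf(clonality, purity, cn, mult) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("purity,cn,expected", [
        (1.0, 2, 1.0),
        (0.5, 1, 0.75),
        (0.5, 4, 1.5),
    ])
    def test_expected_coverage_ratio(self, purity, cn, expected):
        assert expected_coverage_ratio(purity, cn) == pytest.approx(expected)

    def test_het_fraction_one_copy_loss(self):
        # retained allele 1/(2-p), lost allele (1-p)/(2-p)
        assert expected_het_fraction(0.5, 1, 1) == pytest.approx(2 / 3)
        assert expected_het_fraction(0.5, 1, 0) == pytest.approx(1 / 3)
        assert expected_het_fraction(0.7, 2, 1) == pytest.approx(0.5)


class TestPatientTree:
    def test_single_sample_degenerate_tree(self):
        rng = np.random.default_rng(0)
        clades, counts = simulate_patient_tree(["S1"], (50, 10, 5), rng)
        assert clades == [frozenset({"S1"})]
        assert set(counts) == {frozenset({"S1"})}

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_patient_tree([], (50, 10, 5),
                                  np.random.default_rng(0))

    def test_seeded_reproducibility(self):
        a = simulate_patient_tree(["S1", "S2", "S3"], (40, 15, 8),
                                  np.random.default_rng(7))
        b = simulate_patient_tree(["S1", "S2", "S3"], (40, 15, 8),
                                  np.random.default_rng(7))
        assert a == b

    def test_truncal_poisson_mean(self):
        # over 200 patients with truncal mean 50, the mean truncal count
        # must sit within 3 SE of 50
        rng = np.random.default_rng(123)
        counts = []
        for _ in range(200):
            clades, c = simulate_patient_tree(["S1", "S2", "S3"],
                                              (50, 15, 8), rng)
            counts.append(c[frozenset({"S1", "S2", "S3"})])
        se = np.sqrt(50 / 200)
        assert abs(np.mean(counts) - 50) < 3 * se

    def test_clades_are_laminar(self):
        rng = np.random.default_rng(5)
        clades, _ = simulate_patient_tree([f"S{i}" for i in range(4)],
                                          (40, 15, 8), rng)
        for a in clades:
            for b in clades:
                assert a <= b or b <= a or not (a & b)


class TestCoverage:
    def test_neutral_genome_ratio_one(self, reference):
        regions, _ = reference
        rng = np.random.default_rng(1)
        rows = simulate_coverage(regions, [], 1.0, 400, 300.0, rng)
        t = np.array([r.tumor_reads for r in rows], float)
        n = np.array([r.normal_reads for r in rows], float)
        ratio = t.mean() / n.mean()
        assert ratio == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("purity,cn,expected", [(0.5, 1, 0.75),
                                                    (0.5, 4, 1.5)])
    def test_planted_segment_mean_ratio(self, reference, purity, cn,
                                        expected):
        regions, _ = reference
        chrom_regions = [r for r in regions if r.chrom == "2"]
        rng = np.random.default_rng(2)
        segs = [("2", 0, 10**9, cn)]
        rows = simulate_coverage(chrom_regions, segs, purity, 200, 300.0,
                                 rng)
        t = np.array([r.tumor_reads for r in rows], float)
        # tumor mean = depth * expected ratio, within 3 SE
        se = t.std() / np.sqrt(len(t))
        assert abs(t.mean() - 200 * expected) < 3 * se

    def test_invalid_purity_rejected(self, reference):
        regions, _ = reference
        with pytest.raises(ValueError, match="purity"):
            simulate_coverage(regions[:5], [], 0.0, 100, 300.0,
                              np.random.default_rng(0))


class TestVariantReads:
    def test_mean_vaf_matches_closed_form(self):
        rng = np.random.default_rng(3)
        vafs = []
        for _ in range(400):
            tr, ta, nr, na = simulate_variant_reads(
                1.0, 0.4, 2, 1, 100, rng)
            vafs.append(ta / (ta + tr))
        se = np.std(vafs) / np.sqrt(len(vafs))
        assert abs(np.mean(vafs) - 0.2) < 3 * se

    def test_multiplicity_above_cn_rejected(self):
        with pytest.raises(ValueError, match="multiplicity"):
            simulate_variant_reads(1.0, 0.5, 1, 2, 100,
                                   np.random.default_rng(0))


class TestHetSnps:
    def test_balanced_segment_centers_on_half(self, reference):
        regions, _ = reference
        rng = np.random.default_rng(4)
        snps = simulate_het_snps([], 0.8, 500, 100, rng, regions)
        fr = np.array([s.tumor_alt_fraction for s in snps])
        assert abs(fr.mean() - 0.5) < 3 * fr.std() / np.sqrt(len(fr))

    def test_loss_segment_splits_into_two_modes(self, reference):
        regions, _ = reference
        rng = np.random.default_rng(5)
        segs = [("1", 0, 10**9, 1)]
        chrom1 = [r for r in regions if r.chrom == "1"]
        snps = simulate_het_snps(segs, 0.5, 600, 100, rng, chrom1)
        folded = np.array([max(s.tumor_alt_fraction,
                               1 - s.tumor_alt_fraction) for s in snps])
        # retained-allele expectation 2/3 at purity 0.5
        assert np.median(folded) == pytest.approx(2 / 3, abs=0.03)


class TestCohortEmission:
    def test_byte_identical_rerun(self, tmp_path):
        config = SimConfig(n_patients=2, n_multi_sample_patients=1,
                           rng_seed=9)
        emit_cohort(config, tmp_path / "a")
        emit_cohort(config, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_zero_patients_empty_but_valid(self, tmp_path):
        emit_cohort(SimConfig(n_patients=0), tmp_path / "empty")
        meta = (tmp_path / "empty" / "meta.tsv").read_text()
        assert meta.startswith("sample_id")
        assert len(meta.strip().splitlines()) == 1

    def test_default_layout_has_13_multisample_patients(self):
        config = SimConfig()
        truth, obs = simulate_cohort(config)
        multi = [p for p in truth.patients.values()
                 if len(p.sample_ids) >= 2]
        assert len(truth.patients) == 44
        assert len(multi) == 13

    def test_tables_cross_consistent(self, mini_cohort):
        config, truth, obs = mini_cohort
        for sid, tables in obs["tables"].items():
            meta_ids = {m.sample_id for m in obs["meta"]}
            assert sid in meta_ids
            for call in tables["variants"]:
                inside = any(r.chrom == call.chrom
                             and r.start < call.pos <= r.end
                             for r in truth.regions)
                assert inside, f"variant {call.key} outside regions"

    def test_truncal_snvs_present_in_all_samples(self, mini_cohort):
        _, truth, _ = mini_cohort
        for p in truth.patients.values():
            full = frozenset(p.sample_ids)
            for snv in p.snvs:
                assert snv.clade  # every SNV on exactly one edge
                if snv.clade == full:
                    assert all(s in snv.clade for s in p.sample_ids)
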