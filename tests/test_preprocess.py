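import numpy as np
import pytest

from hboscnv.preprocess import bin_profile, correct_gc_bias, extract_read_counts

from conftest import make_profile


class TestBinProfile:
    def test_constant_counts_give_constant_rd(self):
        profile = bin_profile(np.full(40, 7), "A" * 40, bin_size=10)
        assert profile.total_bins == 4
        np.testing.assert_allclose(profile.raw_rd, 7.0)
        np.testing.assert_allclose(profile.gc, 0.0)

    def test_mean_count_per_bin(self):
        profile = bin_profile(np.array([1, 2, 3, 4]), "ACGT", bin_size=4)
        assert profile.raw_rd[0] == pytest.approx(2.5)
        assert profile.gc[0] == pytest.approx(0.5)

    def test_all_n_bin_is_masked_and_excluded_from_n_bins(self):
        seq = "ACGT" + "NNNN" + "ACGT"
        profile = bin_profile(np.ones(12), seq, bin_size=4)
        assert list(profile.n_masked) == [False, True, False]
        assert profile.n_bins == 2
        assert np.isnan(profile.raw_rd[1])

    def test_partial_n_bin_uses_only_non_n_positions(self):
        # one 'N' out of four: below the 50% cutoff, mean over the other 3
        counts = np.array([8, 100, 4, 0])
        profile = bin_profile(counts, "ANGT", bin_size=4)
        assert not profile.n_masked[0]
        assert profile.raw_rd[0] == pytest.approx((8 + 4 + 0) / 3)
        assert profile.gc[0] == pytest.approx(1 / 3)

    def test_binning_conserves_mass(self, rng):
        n = 1000
        counts = rng.integers(0, 50, n)
        seq = rng.choice(list("ACGTN"), n, p=[0.24, 0.24, 0.24, 0.24, 0.04])
        profile = bin_profile(counts, "".join(seq), bin_size=25)
        is_n = seq[: profile.total_bins * 25] == "N"
        usable_pos = 25 - is_n.reshape(-1, 25).sum(axis=1)
        us = profile.usable
        lhs = np.nansum(profile.raw_rd[us] * usable_pos[us])
        rhs = counts[: profile.total_bins * 25][
            ~is_n.reshape(-1)[: profile.total_bins * 25]
        ].sum()
        # masked bins (if any) keep their counts out of both sides
        masked_counts = sum(
            counts[i * 25 : (i + 1) * 25][~is_n[i * 25 : (i + 1) * 25]].sum()
            for i in np.flatnonzero(~us)
        )
        assert lhs == pytest.approx(rhs - masked_counts)

    def test_oversized_bin_falls_back_to_single_bin(self, caplog):
        profile = bin_profile(np.arange(6), "ACGTAC", bin_size=100)
        assert profile.total_bins == 1
        assert profile.raw_rd[0] == pytest.approx(2.5)

    def test_lowercase_reference_handled(self):
        profile = bin_profile(np.ones(4), "acgn", bin_size=4)
        assert profile.gc[0] == pytest.approx(2 / 3)


class TestGCCorrection:
    def test_direct_rescaling_arithmetic(self):
        # stratum A: median 50 with one low bin of 30; stratum B: median 157.
        # Global mean is exactly 100, so the 30-count bin corrects to
        # (100 / 50) * 30 = 60.
        raw = np.array([30.0] + [50.0] * 10 + [157.0] * 10)
        gc = np.array([0.405] * 11 + [0.505] * 10)
        profile = make_profile(raw, gc=gc)
        assert profile.raw_rd.mean() == pytest.approx(100.0)
        out = correct_gc_bias(profile)
        assert out.rd[0] == pytest.approx(60.0)
        np.testing.assert_allclose(out.rd[1:11], 100.0)
        np.testing.assert_allclose(out.rd[11:], 100.0)

    def test_single_stratum_symmetric_values_unchanged(self):
        # all bins share one stratum and the stratum median equals the
        # global mean, so the correction is the identity
        raw = np.tile([90.0, 110.0], 10)
        profile = make_profile(raw, gc=np.full(20, 0.455))
        out = correct_gc_bias(profile)
        np.testing.assert_allclose(out.rd, raw)

    def test_matches_bruteforce_stratum_medians(self, rng):
        raw = rng.uniform(10, 200, 60)
        gc = rng.choice([0.355, 0.405, 0.455], 60)
        profile = make_profile(raw, gc=gc)
        out = correct_gc_bias(profile, stratum_width=0.01, min_stratum_bins=1)
        rbar = raw.mean()
        expected = np.empty_like(raw)
        for i in range(60):
            same = [raw[j] for j in range(60) if abs(gc[j] - gc[i]) < 1e-9]
            expected[i] = rbar / np.median(same) * raw[i]
        np.testing.assert_allclose(out.rd, expected)

    def test_mean_preserved_with_constant_strata(self):
        # each stratum internally constant -> stratum median = stratum mean,
        # so every corrected stratum sits at the global mean
        raw = np.array([50.0] * 15 + [150.0] * 15)
        gc = np.array([0.355] * 15 + [0.555] * 15)
        out = correct_gc_bias(make_profile(raw, gc=gc))
        assert out.rd.mean() == pytest.approx(raw.mean())
        np.testing.assert_allclose(out.rd, raw.mean())

    def test_idempotent_on_flat_gc_profile(self):
        raw = np.full(30, 80.0)
        profile = make_profile(raw, gc=np.full(30, 0.42))
        once = correct_gc_bias(profile)
        twice = correct_gc_bias(once)
        np.testing.assert_allclose(once.rd, twice.rd)

    def test_sparse_stratum_borrows_nearest(self):
        # the lone gc=0.60 bin is below min_stratum_bins and borrows the
        # 0.50 stratum's median instead of its own value
        raw = np.array([100.0] * 12 + [30.0])
        gc = np.array([0.505] * 12 + [0.605])
        out = correct_gc_bias(make_profile(raw, gc=gc), min_stratum_bins=10)
        rbar = raw.mean()
        assert out.rd[-1] == pytest.approx(rbar / 100.0 * 30.0)

    def test_all_masked_raises(self):
        profile = make_profile([1.0, 2.0], masked=[True, True])
        with pytest.raises(ValueError, match="no usable bins"):
            correct_gc_bias(profile)


class TestExtractReadCounts:
    @pytest.fixture
    def bam(self, tmp_path):
        """Tiny coordinate-sorted indexed BAM with known read placements."""
        import pysam

        path = str(tmp_path / "toy.bam")
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chrA", "LN": 500}, {"SN": "chrB", "LN": 300}],
        }
        placements = [("chrA", 10), ("chrA", 10), ("chrA", 99), ("chrB", 5)]
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for i, (chrom, pos) in enumerate(placements):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 20
                a.reference_name = chrom
                a.reference_start = pos
                a.mapping_quality = 40
                a.cigarstring = "20M"
                a.flag = 0
                bam.write(a)
        pysam.index(path)
        return path

    def test_counts_match_placements(self, bam):
        counts = extract_read_counts(bam, "chrA")
        assert counts.sum() == 3
        assert counts[10] == 2
        assert counts[99] == 1

    def test_region_without_reads_is_zero(self, bam):
        counts = extract_read_counts(bam, "chrB")
        assert counts.shape == (300,)
        assert counts[5] == 1
        assert counts[6:].sum() == 0

    def test_mapq_filter(self, bam):
        assert extract_read_counts(bam, "chrA", min_mapq=60).sum() == 0

    def test_missing_chromosome_lists_available(self, bam):
        with pytest.raises(ValueError, match="chrA"):
            extract_read_counts(bam, "chrZ")

    def test_missing_index_is_actionable(self, tmp_path, bam):
        import shutil

        unindexed = str(tmp_path / "unindexed.bam")
        shutil.copy(bam, unindexed)
        with pytest.raises(FileNotFoundError, match="index"):
            extract_read_counts(unindexed, "chrA")
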