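import numpy as np
import pytest

from butlrkit import (
    ChromTable,
    ContactMatrix,
    DegenerateInputError,
    GenomicInterval,
    InvalidParameterError,
    bin_pairs,
    encode_butlr,
    export_bedgraph,
    ice_normalize,
    random_sparse_matrix,
    read_bedgraph,
    virtual_4c,
)


class TestBinPairs:
    def test_single_pair_lands_in_expected_cell(self, chrom_table):
        mats, report = bin_pairs(
            [("r1", "chr1", 10_500, "chr1", 95_000)], chrom_table, 40_000
        )
        m = mats["chr1"]
        assert m.data[0, 2] == 1 and m.nnz == 1  # floor(10500/40k)=0, floor(95000/40k)=2
        assert report.retained == 1

    def test_empty_stream_gives_zero_matrices_and_report(self, chrom_table):
        mats, report = bin_pairs([], chrom_table, 40_000)
        assert report.total == report.retained == 0
        assert all(not m.nnz for m in mats.values()) or not mats

    def test_inter_pair_dropped_when_same_chrom_only(self, chrom_table):
        stream = [
            ("r1", "chr1", 100, "chr2", 100),
            ("r2", "chr1", 100, "chr1", 50_000),
        ]
        mats, report = bin_pairs(stream, chrom_table, 40_000, same_chrom_only=True)
        assert report.retained == 1 and report.inter_dropped == 1
        assert ("chr1", "chr2") not in mats

    def test_inter_matrix_produced_when_filter_off(self, chrom_table):
        stream = [("r1", "chr2", 100, "chr1", 100)]  # reversed orientation on input
        mats, report = bin_pairs(stream, chrom_table, 40_000, same_chrom_only=False)
        assert mats[("chr1", "chr2")].data[0, 0] == 1

    def test_reads_are_conserved_across_categories(self, chrom_table, tmp_path):
        p = tmp_path / "mixed.pairs"
        p.write_text(
            "# comment\n"
            "r1\tchr1\t100\tchr1\t200\t+\t-\t60\t60\n"
            "r2\tchr1\t100\tchr1\t200\t+\t-\t5\t60\n"   # low mapq
            "r3\tchrZ\t100\tchr1\t200\t+\t-\t60\t60\n"  # unknown chromosome
            "r4\tchr1\t100\tchr1\t9999999\t+\t-\t60\t60\n"  # out of range
            "r5\tchr1\t100\tchr2\t200\t+\t-\t60\t60\n"  # inter, dropped
        )
        mats, report = bin_pairs(p, chrom_table, 40_000, mapq_min=30)
        assert report.total == 5
        assert (report.low_mapq, report.unknown_chrom, report.out_of_range,
                report.inter_dropped) == (1, 1, 1, 1)
        assert report.retained + report.rejected() == report.total
        assert mats["chr1"].sum() == 1

    def test_mapq_filter_skipped_without_mapq_columns(self, chrom_table, tmp_path):
        p = tmp_path / "nomapq.pairs"
        p.write_text("r1\tchr1\t100\tchr1\t200\t+\t-\n")
        _, report = bin_pairs(p, chrom_table, 40_000, mapq_min=30)
        assert report.retained == 1 and report.low_mapq == 0

    def test_intra_pairs_folded_to_upper_triangle(self, chrom_table):
        stream = [("r1", "chr1", 95_000, "chr1", 10_500)]  # second mate upstream
        mats, _ = bin_pairs(stream, chrom_table, 40_000)
        assert mats["chr1"].data[0, 2] == 1


class TestIceNormalize:
    def test_equal_row_sums_are_a_fixed_point(self):
        n = 40
        dense = np.ones((n, n))
        m = ContactMatrix.from_dense("chr1", "chr1", 10_000, dense)
        normalized, bias = ice_normalize(m)
        live = ~bias.mask
        assert np.allclose(bias.bias[live], 1.0, atol=1e-4)
        assert np.allclose(normalized.to_dense(), dense, rtol=1e-4)

    def test_planted_bias_recovered(self, rng):
        n = 300
        b = np.exp(rng.normal(0, 0.5, n))
        m = ContactMatrix.from_dense("chr1", "chr1", 10_000, np.outer(b, b) * 4.0)
        _, bias = ice_normalize(m)
        live = ~bias.mask
        corr = np.corrcoef(bias.bias[live], b[live])[0, 1]
        assert corr > 0.99
        assert bias.converged

    def test_row_sum_cv_and_total_preserved(self, rng):
        n = 200
        b = np.exp(rng.normal(0, 0.3, n))
        raw = rng.poisson(np.outer(b, b) * 20).astype(float)
        raw = np.triu(raw) + np.triu(raw, 1).T
        m = ContactMatrix.from_dense("chr1", "chr1", 10_000, raw)
        normalized, bias = ice_normalize(m, tol=1e-8)
        live = ~bias.mask
        sums = normalized.to_dense().sum(axis=1)[live]
        assert sums.std() / sums.mean() < 1e-3
        assert np.isclose(normalized.sum(), m.sum())

    def test_zero_pattern_preserved(self, rng):
        m = random_sparse_matrix(100, 0.05, seed=3, resolution=10_000)
        normalized, _ = ice_normalize(m)
        assert np.array_equal(m.to_dense() == 0, normalized.to_dense() == 0)

    def test_biases_have_unit_geometric_mean(self, rng):
        m = random_sparse_matrix(150, 0.3, seed=8, resolution=10_000)
        _, bias = ice_normalize(m)
        live = ~bias.mask
        assert np.isclose(np.exp(np.mean(np.log(bias.bias[live]))), 1.0)

    def test_all_masked_is_degenerate(self):
        import scipy.sparse as sp

        m = ContactMatrix("chr1", "chr1", 10_000, 10, 10, sp.csr_matrix((10, 10)))
        with pytest.raises(DegenerateInputError):
            ice_normalize(m)

    def test_non_convergence_warns_but_returns(self, rng):
        m = random_sparse_matrix(100, 0.1, seed=5, resolution=10_000)
        with pytest.warns(UserWarning, match="did not converge"):
            _, bias = ice_normalize(m, tol=1e-12, max_iter=1)
        assert not bias.converged

    def test_inter_matrix_rejected(self):
        m = random_sparse_matrix(20, 0.2, seed=1, chrom_a="chr1", chrom_b="chr2",
                                 resolution=10_000)
        with pytest.raises(InvalidParameterError):
            ice_normalize(m)


class TestVirtual4C:
    @pytest.fixture
    def source(self):
        return random_sparse_matrix(100, 0.3, seed=7, resolution=10_000)

    def test_single_bin_bait_equals_matrix_row(self, source):
        res = 10_000
        bait = GenomicInterval("chr1", 40 * res, 41 * res)
        window = GenomicInterval("chr1", 10 * res, 90 * res)
        track = virtual_4c(source, bait, window, smooth_bins=1)
        assert np.array_equal(track.signal, source.to_dense()[40, 10:90])

    def test_bait_self_signal_is_diagonal_entry(self, source):
        res = 10_000
        bait = GenomicInterval("chr1", 40 * res, 41 * res)
        track = virtual_4c(source, bait, GenomicInterval("chr1", 30 * res, 50 * res))
        assert track.signal[10] == source.to_dense()[40, 40]

    def test_multi_bin_bait_is_mean_of_bait_rows(self, source):
        res = 10_000
        bait = GenomicInterval("chr1", 40 * res, 44 * res)
        window = GenomicInterval("chr1", 0, 100 * res)
        track = virtual_4c(source, bait, window)
        assert np.allclose(track.signal, source.to_dense()[40:44].mean(axis=0))

    def test_smoothing_is_truncated_moving_average(self, source):
        res = 10_000
        bait = GenomicInterval("chr1", 40 * res, 41 * res)
        window = GenomicInterval("chr1", 30 * res, 50 * res)
        raw = virtual_4c(source, bait, window).signal
        sm = virtual_4c(source, bait, window, smooth_bins=3).signal
        assert np.isclose(sm[0], raw[:2].mean())          # edge: 2-bin window
        assert np.isclose(sm[5], raw[4:7].mean())
        with pytest.raises(InvalidParameterError):
            virtual_4c(source, bait, window, smooth_bins=2)

    def test_butlr_source_matches_matrix_source(self, source, chrom_table, tmp_path):
        ct = ChromTable([("chr1", 100 * 10_000)])
        f = encode_butlr([source], ct, 10_000, tmp_path / "v.butlr")
        res = 10_000
        bait = GenomicInterval("chr1", 12 * res, 13 * res)
        window = GenomicInterval("chr1", 0, 60 * res)
        t_file = virtual_4c(f, bait, window)
        t_mat = virtual_4c(source, bait, window)
        assert np.array_equal(t_file.signal, t_mat.signal)
        f.close()


class TestBedgraph:
    def test_bin_intervals_and_explicit_zeros(self, tmp_path):
        m = random_sparse_matrix(10, 0.3, seed=2, resolution=40_000)
        bait = GenomicInterval("chr1", 0, 40_000)
        window = GenomicInterval("chr1", 0, 120_000)
        track = virtual_4c(m, bait, window)
        p = tmp_path / "t.bedgraph"
        export_bedgraph(track, p)
        df = read_bedgraph(p)
        assert len(df) == 3  # zero bins written explicitly
        assert df["start"].tolist() == [0, 40_000, 80_000]
        assert df["end"].tolist() == [40_000, 80_000, 120_000]

    def test_signal_round_trip(self, tmp_path):
        m = random_sparse_matrix(50, 0.3, seed=4, resolution=10_000)
        track = virtual_4c(m, GenomicInterval("chr1", 100_000, 110_000),
                           GenomicInterval("chr1", 0, 500_000))
        p = tmp_path / "rt.bedgraph"
        export_bedgraph(track, p)
        back = read_bedgraph(p)["value"].to_numpy()
        assert np.allclose(back, track.signal, rtol=1e-5)
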