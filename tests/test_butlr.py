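import struct

import numpy as np
import pytest

from butlrkit import (
    ButlrFile,
    ContactMatrix,
    EncodingError,
    FormatError,
    GenomicInterval,
    InvalidParameterError,
    NotFoundError,
    encode_butlr,
    random_sparse_matrix,
    read_header,
    read_matrix_text,
    validate_butlr,
    write_matrix_text,
)
from butlrkit.butlr import MAGIC


def _iv(chrom, b0, b1, res=40_000):
    return GenomicInterval(chrom, b0 * res, b1 * res)


@pytest.fixture
def genome_file(chrom_table, tmp_path):
    """Encoded file with two intra matrices and one inter matrix at 40 kb."""
    m1 = random_sparse_matrix(60, 0.10, seed=1, chrom_a="chr1", resolution=40_000)
    m2 = random_sparse_matrix(40, 0.15, seed=2, chrom_a="chr2", resolution=40_000)
    mi = random_sparse_matrix(60, 0.05, seed=3, chrom_a="chr1", chrom_b="chr2",
                              n_cols=40, resolution=40_000)
    path = tmp_path / "g.butlr"
    f = encode_butlr([m1, m2, mi], chrom_table, 40_000, path, assembly="toy")
    yield f, {"chr1": m1, "chr2": m2, ("chr1", "chr2"): mi}, path
    f.close()


class TestEncode:
    def test_symmetry_fold_stores_lower_triple_once(self, chrom_table, tmp_path):
        m = ContactMatrix.from_coo("chr1", "chr1", 40_000, 60, 60, [5], [2], [7.0])
        assert m.data[2, 5] == 7.0 and m.nnz == 1
        f = encode_butlr([m], chrom_table, 40_000, tmp_path / "f.butlr")
        assert f.decode_matrix("chr1").data[2, 5] == 7.0
        f.close()

    def test_conflicting_symmetric_duplicates_are_an_error(self):
        with pytest.raises(EncodingError):
            ContactMatrix.from_coo("chr1", "chr1", 40_000, 60, 60,
                                   [2, 5], [5, 2], [7.0, 8.0])

    def test_consistent_symmetric_duplicates_stored_once(self):
        m = ContactMatrix.from_coo("chr1", "chr1", 40_000, 60, 60,
                                   [2, 5], [5, 2], [7.0, 7.0])
        assert m.nnz == 1 and m.data[2, 5] == 7.0

    def test_all_zero_matrix_has_flat_row_index_and_zero_queries(
        self, chrom_table, tmp_path
    ):
        import scipy.sparse as sp

        m = ContactMatrix("chr1", "chr1", 40_000, 60, 60, sp.csr_matrix((60, 60)))
        f = encode_butlr([m], chrom_table, 40_000, tmp_path / "z.butlr")
        entry = f.header.directory["chr1"]
        offs = f._row_offsets(entry, 0, 60)
        assert len(set(offs.tolist())) == 1  # 61 equal offsets
        assert not f.query(_iv("chr1", 0, 60)).any()
        f.close()

    def test_resolution_mismatch_rejected(self, chrom_table, tmp_path):
        m = random_sparse_matrix(60, 0.1, seed=1, resolution=10_000)
        with pytest.raises(InvalidParameterError):
            encode_butlr([m], chrom_table, 40_000, tmp_path / "bad.butlr")

    def test_round_trip_float32_exact(self, tmp_path):
        from butlrkit import ChromTable

        ct = ChromTable([("chr1", 500 * 10_000)])
        m = random_sparse_matrix(500, 0.01, seed=9, resolution=10_000)
        f = encode_butlr([m], ct, 10_000, tmp_path / "rt.butlr")
        assert f.decode_matrix("chr1") == m  # integer values survive float32
        f.close()


class TestHeader:
    def test_metadata_round_trip_without_payload_read(self, genome_file):
        _, _, path = genome_file
        h = read_header(path)
        assert h.resolution == 40_000
        assert h.assembly == "toy"
        assert h.chrom_table.names == ["chr1", "chr2"]

    def test_directory_has_two_intra_and_one_pair_key(self, genome_file):
        _, _, path = genome_file
        h = read_header(path)
        assert set(h.directory) == {"chr1", "chr2", ("chr1", "chr2")}

    def test_bad_magic_is_a_format_error(self, genome_file, tmp_path):
        _, _, path = genome_file
        raw = bytearray(path.read_bytes())
        raw[:4] = b"WHAT"
        bad = tmp_path / "bad.butlr"
        bad.write_bytes(raw)
        with pytest.raises(FormatError):
            read_header(bad)

    def test_truncated_header_is_a_corruption_error(self, genome_file, tmp_path):
        from butlrkit import CorruptFileError

        _, _, path = genome_file
        bad = tmp_path / "trunc.butlr"
        bad.write_bytes(path.read_bytes()[:12])
        with pytest.raises(CorruptFileError):
            read_header(bad)


class TestQuery:
    def test_full_chromosome_query_equals_decoded_matrix(self, genome_file):
        f, mats, _ = genome_file
        assert np.array_equal(f.query(_iv("chr1", 0, 60)), mats["chr1"].to_dense())

    def test_intra_result_is_symmetric(self, genome_file):
        f, _, _ = genome_file
        block = f.query(_iv("chr1", 10, 30))
        assert np.array_equal(block, block.T)

    def test_missing_second_region_means_square_view(self, genome_file):
        f, _, _ = genome_file
        a = _iv("chr1", 5, 25)
        assert np.array_equal(f.query(a), f.query(a, a))

    def test_unknown_pair_is_not_found(self, genome_file):
        f, _, _ = genome_file
        with pytest.raises(NotFoundError):
            f.query(GenomicInterval("chr9", 0, 10))

    def test_random_queries_match_brute_force_slices(self, genome_file, rng):
        f, mats, _ = genome_file
        res = 40_000
        dense = {k: m.to_dense() for k, m in mats.items()}
        chroms = {"chr1": 60, "chr2": 40}
        for _ in range(60):
            ca, cb = rng.choice(["chr1", "chr2"], size=2)
            na, nb = chroms[ca], chroms[cb]
            a0, a1 = sorted(rng.choice(na + 1, size=2, replace=False))
            b0, b1 = sorted(rng.choice(nb + 1, size=2, replace=False))
            a = GenomicInterval(ca, a0 * res + int(rng.integers(res)), a1 * res)
            b = GenomicInterval(cb, b0 * res + int(rng.integers(res)), b1 * res)
            got = f.query(a, b)
            if ca == cb:
                want = dense[ca][a0:a1, b0:b1]
            elif (ca, cb) in dense:
                want = dense[(ca, cb)][a0:a1, b0:b1]
            else:
                want = dense[(cb, ca)][b0:b1, a0:a1].T
            assert np.array_equal(got, want), (a, b)

    def test_io_locality_small_query_reads_small_fraction(self, tmp_path):
        from butlrkit import ChromTable

        n, res = 2_000, 10_000
        ct = ChromTable([("chr1", n * res)])
        m = random_sparse_matrix(n, 0.01, seed=4, resolution=res)
        path = tmp_path / "loc.butlr"
        encode_butlr([m], ct, res, path).close()
        f = ButlrFile(path)
        f.reset_io_counter()
        f.query(_iv("chr1", 1000, 1020, res))  # 1% of rows
        frac = f.bytes_read / f.file_size
        assert frac < 0.05, f"read {frac:.1%} of the file"
        f.close()


class TestValidate:
    def test_fresh_file_has_no_violations(self, genome_file):
        _, _, path = genome_file
        assert validate_butlr(path).ok

    def test_unsorted_columns_detected_with_row_named(self, genome_file, tmp_path):
        f, _, path = genome_file
        entry = f.header.directory["chr1"]
        # find a row with >= 2 columns and swap its first two column ids
        offs = f._row_offsets(entry, 0, entry.n_rows)
        raw = bytearray(path.read_bytes())
        target_row = None
        for r in range(entry.n_rows):
            lo, hi = int(offs[r]), int(offs[r + 1])
            if hi - lo >= 4 + 16:
                target_row = r
                c0, c1 = struct.unpack_from("<II", raw, lo + 4)
                struct.pack_into("<II", raw, lo + 4, c1, c0)
                break
        assert target_row is not None
        bad = tmp_path / "unsorted.butlr"
        bad.write_bytes(raw)
        report = validate_butlr(bad)
        assert len(report.violations) == 1
        assert f"row {target_row}" in report.violations[0]
        assert "increasing" in report.violations[0]

    def test_truncated_payload_detected(self, genome_file, tmp_path):
        _, _, path = genome_file
        bad = tmp_path / "trunc.butlr"
        bad.write_bytes(path.read_bytes()[:-200])
        report = validate_butlr(bad)
        assert any("truncated" in v for v in report.violations)


class TestMatrixText:
    def test_dense_text_round_trip(self, tmp_path):
        m = random_sparse_matrix(30, 0.2, seed=5, resolution=40_000)
        p = tmp_path / "dense.tsv"
        write_matrix_text(m, p)
        back = read_matrix_text(p, "chr1", 40_000)
        assert back == m

    def test_sparse_triples_round_trip(self, tmp_path):
        m = random_sparse_matrix(30, 0.2, seed=6, resolution=40_000)
        p = tmp_path / "sparse.tsv"
        write_matrix_text(m, p, sparse=True)
        back = read_matrix_text(p, "chr1", 40_000, n_rows=30, n_cols=30)
        assert back == m

    def test_chrom_start_labels_in_triples(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("chr1:0\tchr1:80000\t3.5\nchr1:80000\tchr1:80000\t2\n")
        m = read_matrix_text(p, "chr1", 40_000, n_rows=5, n_cols=5)
        assert m.data[0, 2] == 3.5 and m.data[2, 2] == 2

    def test_dense_text_with_header_labels(self, tmp_path):
        p = tmp_path / "hdr.tsv"
        p.write_text(
            "label\tbin0\tbin1\tbin2\n"
            "r0\t1\t2\t0\n"
            "r1\t2\t5\t0\n"
            "r2\t0\t0\t4\n"
        )
        m = read_matrix_text(p, "chr1", 40_000)
        assert m.n_rows == 3 and m.data[0, 1] == 2 and m.data[2, 2] == 4
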