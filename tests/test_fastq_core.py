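"""FASTQ parsing, Phred decoding, and the mergeable statistics monoid."""

import gzip
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqstat.fastq_core import (
    FastqParseError,
    FastqRecord,
    QualityEncodingError,
    SegmentStats,
    StatsMergeError,
    compute_segment_stats,
    decode_quality,
    index_records,
    merge_stats,
    open_fastq,
    parse_fastq,
    stats_for_file,
)


class TestParse:
    def test_two_records(self, fastq_text):
        recs = list(parse_fastq(io.StringIO(fastq_text)))
        assert [r.id for r in recs] == ["r1", "r2"]
        assert recs[0].sequence == "ACGT"
        assert recs[0].quality == "II!!"

    def test_gzip_roundtrip_identical(self, fastq_text):
        blob = gzip.compress(fastq_text.encode())
        plain = list(parse_fastq(io.StringIO(fastq_text)))
        packed = list(parse_fastq(io.BytesIO(blob), compressed=True))
        assert plain == packed

    def test_reserialization_reproduces_input(self, fastq_text):
        recs = parse_fastq(io.StringIO(fastq_text))
        assert "".join(r.to_fastq() for r in recs) == fastq_text

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("@r1\nACGT\n+\nIII\n", "record 1"),  # length mismatch
            ("@r1\nACGT\nIIII\nIIII\n", "separator"),  # missing '+'
            ("rX\nACGT\n+\nIIII\n", "'@'"),  # bad header
            ("@r1\nACGT\n+\nIIII\n@r2\nAC\n", "record 2"),  # truncated
        ],
    )
    def test_malformed_records_name_ordinal_and_violation(self, text, fragment):
        with pytest.raises(FastqParseError, match=fragment):
            list(parse_fastq(io.StringIO(text)))


class TestDecode:
    @pytest.mark.parametrize(
        "char,offset,score", [("I", 33, 40), ("!", 33, 0), ("h", 64, 40)]
    )
    def test_decode(self, char, offset, score):
        assert decode_quality(char, offset) == score

    def test_below_offset_is_error(self):
        with pytest.raises(QualityEncodingError):
            decode_quality("!", 64)


class TestSegmentStats:
    def test_hand_arithmetic(self):
        rec = FastqRecord("r", "ACGT", "II!!")
        s = compute_segment_stats([rec], q_threshold=25, offset=33)
        assert (s.n_reads, s.n_bases, s.qual_sum, s.hq_bases) == (1, 4, 80, 2)
        assert s.hq_percent == 50.0
        assert s.mean_quality == 20.0

    def test_empty_iterator_is_identity(self):
        s = compute_segment_stats([])
        assert s == SegmentStats.empty()
        assert s.n_reads == 0

    def test_uniform_quality_all_high(self):
        # 1000 reads at constant score 30 > Q=25; brute-force re-check.
        recs = [FastqRecord(f"r{i}", "A" * 50, chr(30 + 33) * 50) for i in range(1000)]
        s = compute_segment_stats(recs, q_threshold=25)
        brute_sum = sum(ord(c) - 33 for r in recs for c in r.quality)
        brute_hq = sum(1 for r in recs for c in r.quality if ord(c) - 33 > 25)
        assert s.qual_sum == brute_sum == 30 * 50_000
        assert s.hq_bases == brute_hq
        assert s.hq_percent == 100.0

    def test_threshold_boundary_is_strict(self):
        rec = FastqRecord("r", "AA", chr(25 + 33) * 2)
        assert compute_segment_stats([rec], q_threshold=25).hq_bases == 0
        assert compute_segment_stats([rec], q_threshold=25, inclusive=True).hq_bases == 2

    def test_hq_nonincreasing_in_q(self):
        recs = [FastqRecord(f"r{i}", "ACGTA", "!(2<F") for i in range(3)]
        counts = [compute_segment_stats(recs, q_threshold=q).hq_bases for q in range(42)]
        assert counts == sorted(counts, reverse=True)


qual_chars = st.text(
    alphabet=st.characters(min_codepoint=33, max_codepoint=74), min_size=1, max_size=30
)


@st.composite
def record_lists(draw):
    quals = draw(st.lists(qual_chars, min_size=0, max_size=40))
    return [FastqRecord(f"r{i}", "A" * len(q), q) for i, q in enumerate(quals)]


class TestMerge:
    def test_identity_and_threshold_guard(self):
        a = compute_segment_stats([FastqRecord("r", "AC", "II")])
        assert merge_stats(a, SegmentStats.empty()) == a
        with pytest.raises(StatsMergeError):
            merge_stats(a, SegmentStats.empty(q_threshold=30))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(record_lists(), st.integers(1, 8), st.data())
    def test_segmentation_independence(self, records, k, data):
        """Folding any record-aligned split equals the single-pass result."""
        whole = compute_segment_stats(records)
        cuts = sorted(
            data.draw(
                st.lists(st.integers(0, len(records)), min_size=k - 1, max_size=k - 1)
            )
        )
        edges = [0] + cuts + [len(records)]
        acc = SegmentStats.empty()
        for lo, hi in zip(edges[:-1], edges[1:]):
            acc = merge_stats(acc, compute_segment_stats(records[lo:hi]))
        assert acc == whole

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(record_lists(), record_lists())
    def test_commutativity(self, ra, rb):
        a, b = compute_segment_stats(ra), compute_segment_stats(rb)
        assert merge_stats(a, b) == merge_stats(b, a)


class TestFileLevel:
    def test_matches_biopython_oracle(self, small_manifest):
        """Independent parse + tally via Biopython agrees on every fixture file."""
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        for _, fspec in small_manifest.entries[:3]:
            ours = stats_for_file(fspec.path)
            n = bases = qsum = hq = 0
            with open(fspec.path) as fh:
                for _, seq, qual in FastqGeneralIterator(fh):
                    n += 1
                    bases += len(seq)
                    scores = [ord(c) - 33 for c in qual]
                    qsum += sum(scores)
                    hq += sum(1 for s in scores if s > 25)
            assert (ours.n_reads, ours.n_bases, ours.qual_sum, ours.hq_bases) == (
                n, bases, qsum, hq,
            )

    def test_index_records_offsets_are_record_starts(self, small_manifest):
        path = small_manifest.entries[0][1].path
        offsets = index_records(path)
        n_records = stats_for_file(path).n_reads
        assert len(offsets) == n_records + 1
        with open(path, "rb") as fh:
            for off in offsets[:-1]:
                fh.seek(off)
                assert fh.read(1) == b"@"

    def test_truncated_file_is_hard_error(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nAC\n")
        with pytest.raises(FastqParseError):
            stats_for_file(bad)
        with pytest.raises(FastqParseError):
            index_records(bad)

    def test_open_fastq_detects_gzip_by_magic(self, tmp_path, fastq_text):
        # gzip payload under a non-.gz name must still decompress
        path = tmp_path / "misnamed.fastq"
        path.write_bytes(gzip.compress(fastq_text.encode()))
        with open_fastq(path) as fh:
            assert len(list(parse_fastq(fh))) == 2
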