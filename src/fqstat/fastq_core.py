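"""FASTQ parsing, Phred decoding, and mergeable per-segment statistics.

A FASTQ record occupies exactly four lines: a header starting with ``@``,
the base sequence, a separator line starting with ``+``, and a per-base
quality string of the same length as the sequence.  Quality characters
encode integer Phred scores as ``chr(score + offset)`` with offset 33
(Sanger/modern Illumina) or 64 (legacy Illumina).

The central container is :class:`SegmentStats`, an accumulator of
read/length/quality tallies over a stretch of records.  It forms a
commutative monoid under :func:`merge_stats` with :meth:`SegmentStats.empty`
as identity, which is what allows a file to be processed in record-aligned
segments by independent workers and the partial results folded back into
exactly the single-pass answer.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, replace
from typing import IO, Iterable, Iterator, Union

import numpy as np

GZIP_MAGIC = b"\x1f\x8b"

#: Default Phred threshold above which a base counts as high quality.
DEFAULT_Q = 25.0

#: Default ASCII offset of the quality encoding (Sanger / Phred+33).
DEFAULT_PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """A malformed FASTQ record (ordinal and violation carried in the message)."""


class QualityEncodingError(ValueError):
    """A quality character below the declared ASCII offset."""


class StatsMergeError(ValueError):
    """Attempt to merge statistics computed under different Q thresholds."""


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read: header (without the leading ``@``), bases, qualities."""

    id: str
    sequence: str
    quality: str

    def to_fastq(self) -> str:
        """Serialize back to the canonical 4-line representation."""
        return f"@{self.id}\n{self.sequence}\n+\n{self.quality}\n"


def is_gzip_path(path: Union[str, os.PathLike]) -> bool:
    """Detect gzip input by extension, confirmed (or overridden) by magic bytes."""
    path = os.fspath(path)
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
    except OSError:
        return path.endswith(".gz")
    return magic == GZIP_MAGIC


def open_fastq(path: Union[str, os.PathLike]) -> IO[str]:
    """Open a FASTQ file for text reading, transparently decompressing gzip."""
    if is_gzip_path(path):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def parse_fastq(
    stream: Union[IO[str], IO[bytes], Iterable[str]],
    compressed: bool = False,
) -> Iterator[FastqRecord]:
    """Yield :class:`FastqRecord` from a FASTQ text/byte stream.

    Parameters
    ----------
    stream:
        An iterable of lines (text or bytes).  With ``compressed=True`` the
        stream must be a binary file object carrying gzip framing.
    compressed:
        Decompress the stream with gzip before parsing.

    Raises
    ------
    FastqParseError
        On a sequence/quality length mismatch, a missing ``+`` separator,
        a header not starting with ``@``, or a truncated final record.  The
        message names the 1-based record ordinal and the violation.
    """
    if compressed:
        stream = io.TextIOWrapper(gzip.GzipFile(fileobj=stream), encoding="ascii")

    lines = iter(stream)
    ordinal = 0
    while True:
        header = _next_line(lines)
        if header is None:
            return
        ordinal += 1
        if not header.startswith("@"):
            raise FastqParseError(
                f"record {ordinal}: header line does not start with '@': {header!r}"
            )
        seq = _next_line(lines)
        plus = _next_line(lines)
        qual = _next_line(lines)
        if qual is None:
            raise FastqParseError(f"record {ordinal}: truncated record at end of input")
        if not plus.startswith("+"):
            raise FastqParseError(
                f"record {ordinal}: separator line does not start with '+': {plus!r}"
            )
        if len(seq) != len(qual):
            raise FastqParseError(
                f"record {ordinal}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        if not seq:
            raise FastqParseError(f"record {ordinal}: empty sequence")
        yield FastqRecord(id=header[1:], sequence=seq, quality=qual)


def _next_line(lines) -> Union[str, None]:
    # Skips blank lines (tolerated only between records / at EOF; a blank line
    # inside a record surfaces as a violation on a later field).
    for raw in lines:
        if isinstance(raw, bytes):
            raw = raw.decode("ascii")
        line = raw.rstrip("\r\n")
        if line:
            return line
    return None


def decode_quality(q_char: str, offset: int = DEFAULT_PHRED_OFFSET) -> int:
    """Decode one quality character to its integer Phred score.

    ``score = ord(q_char) - offset`` with offset 33 or 64.
    """
    if offset not in (33, 64):
        raise ValueError(f"Phred offset must be 33 or 64, got {offset}")
    score = ord(q_char) - offset
    if score < 0:
        raise QualityEncodingError(
            f"quality character {q_char!r} (ASCII {ord(q_char)}) below offset {offset}"
        )
    return score


@dataclass(frozen=True)
class SegmentStats:
    """Mergeable tallies of read/length/quality statistics for a record stretch.

    All fields are exact integer tallies except ``q_threshold`` (the Q the
    high-quality count was computed against).  Derived metrics are exposed as
    properties and return ``nan`` on the empty accumulator.
    """

    n_reads: int = 0
    n_bases: int = 0
    len_min: int = 0
    len_max: int = 0
    len_sum: int = 0
    qual_sum: int = 0
    hq_bases: int = 0
    q_threshold: float = DEFAULT_Q

    @classmethod
    def empty(cls, q_threshold: float = DEFAULT_Q) -> "SegmentStats":
        return cls(q_threshold=q_threshold)

    @property
    def mean_length(self) -> float:
        return self.len_sum / self.n_reads if self.n_reads else float("nan")

    @property
    def mean_quality(self) -> float:
        return self.qual_sum / self.n_bases if self.n_bases else float("nan")

    @property
    def hq_percent(self) -> float:
        return 100.0 * self.hq_bases / self.n_bases if self.n_bases else float("nan")


def compute_segment_stats(
    records: Iterable[FastqRecord],
    q_threshold: float = DEFAULT_Q,
    offset: int = DEFAULT_PHRED_OFFSET,
    inclusive: bool = False,
) -> SegmentStats:
    """Tally statistics over an iterator of records.

    A base is high quality when its decoded score is strictly greater than
    ``q_threshold`` (or ``>=`` with ``inclusive=True``).
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be non-negative")
    n_reads = n_bases = len_sum = qual_sum = hq_bases = 0
    len_min = len_max = 0
    for rec in records:
        arr = np.frombuffer(rec.quality.encode("ascii"), dtype=np.uint8)
        if arr.size and int(arr.min()) < offset:
            bad = chr(int(arr.min()))
            raise QualityEncodingError(
                f"read {rec.id!r}: quality character {bad!r} below offset {offset}"
            )
        scores = arr.astype(np.int64) - offset
        n = arr.size
        if n_reads == 0:
            len_min = len_max = n
        else:
            len_min = min(len_min, n)
            len_max = max(len_max, n)
        n_reads += 1
        n_bases += n
        len_sum += n
        qual_sum += int(scores.sum())
        if inclusive:
            hq_bases += int((scores >= q_threshold).sum())
        else:
            hq_bases += int((scores > q_threshold).sum())
    return SegmentStats(
        n_reads=n_reads,
        n_bases=n_bases,
        len_min=len_min,
        len_max=len_max,
        len_sum=len_sum,
        qual_sum=qual_sum,
        hq_bases=hq_bases,
        q_threshold=q_threshold,
    )


def merge_stats(a: SegmentStats, b: SegmentStats) -> SegmentStats:
    """Combine two segment accumulators; associative and commutative.

    The empty accumulator is the identity.  Merging statistics computed
    under different Q thresholds is refused: the high-quality tallies would
    not be comparable.
    """
    if a.q_threshold != b.q_threshold:
        raise StatsMergeError(
            f"cannot merge stats with Q={a.q_threshold} and Q={b.q_threshold}"
        )
    if a.n_reads == 0:
        return replace(b)
    if b.n_reads == 0:
        return replace(a)
    return SegmentStats(
        n_reads=a.n_reads + b.n_reads,
        n_bases=a.n_bases + b.n_bases,
        len_min=min(a.len_min, b.len_min),
        len_max=max(a.len_max, b.len_max),
        len_sum=a.len_sum + b.len_sum,
        qual_sum=a.qual_sum + b.qual_sum,
        hq_bases=a.hq_bases + b.hq_bases,
        q_threshold=a.q_threshold,
    )


def stats_for_file(
    path: Union[str, os.PathLike],
    q_threshold: float = DEFAULT_Q,
    offset: int = DEFAULT_PHRED_OFFSET,
    inclusive: bool = False,
) -> SegmentStats:
    """Single-pass whole-file statistics (the serial reference computation)."""
    with open_fastq(path) as fh:
        return compute_segment_stats(
            parse_fastq(fh), q_threshold=q_threshold, offset=offset, inclusive=inclusive
        )


def index_records(path: Union[str, os.PathLike]) -> list[int]:
    """Byte offsets of record starts in a plain (uncompressed) FASTQ file.

    Returns ``[o_0, o_1, ..., o_n]`` where ``o_i`` is the offset of record
    ``i`` and ``o_n`` is the file size, so record ``i`` spans
    ``[o_i, o_{i+1})``.  Needed because a byte-budget segment boundary must
    be advanced to the next record start: a ``@`` may legitimately begin a
    quality line, so offsets cannot be inferred from content alone.
    """
    offsets = [0]
    pos = 0
    with open(path, "rb") as fh:
        line_no = 0
        for raw in fh:
            pos += len(raw)
            if raw.strip():
                line_no += 1
                if line_no % 4 == 0:
                    offsets.append(pos)
    if line_no % 4 != 0:
        raise FastqParseError(
            f"record {line_no // 4 + 1}: truncated record at end of input"
        )
    if offsets[-1] != pos:
        offsets.append(pos)  # trailing blank lines belong to the last record
    return offsets
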