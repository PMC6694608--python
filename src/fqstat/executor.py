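"""Execute an allocation plan with concurrent workers and a deterministic merge.

Each file in a plan is cut into record-aligned work units: one unit per
(pass, core-chunk).  A pass's byte budget (pass fraction x file size) is
advanced to the next record start so no unit ever splits a 4-line record;
within a pass, a file assigned k cores is partitioned into k contiguous
record chunks balanced by record count.  Workers own disjoint units and
emit immutable partial statistics; assembly is a pure fold of
:func:`~fqstat.fastq_core.merge_stats` in a fixed (file, pass, chunk)
order, so the final result is identical to a serial single-pass run for
any worker budget and any completion order.

Plain files are read by byte range (seek); gzip files cannot be
random-accessed by byte offset, so their units carry record-count ranges
and each worker streams from the start of the file, skipping to its range.

A corrupt file aborts only its own result: the error is recorded per file
and all other results are unaffected.
"""

from __future__ import annotations

import io
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from itertools import islice
from typing import Mapping, Optional, Union

from .fastq_core import (
    DEFAULT_PHRED_OFFSET,
    DEFAULT_Q,
    SegmentStats,
    compute_segment_stats,
    index_records,
    is_gzip_path,
    merge_stats,
    open_fastq,
    parse_fastq,
)
from .scheduler import AllocationPlan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkUnit:
    """One worker's share of one pass over one file.

    For plain files ``start_byte``/``end_byte`` delimit a record-aligned
    half-open byte interval; for gzip files ``start_record``/``end_record``
    delimit a half-open record interval in stream order.
    """

    path: str
    pass_index: int
    chunk_index: int
    start_byte: int = 0
    end_byte: int = 0
    start_record: int = 0
    end_record: int = 0
    compressed: bool = False


@dataclass(frozen=True)
class PerfRecord:
    """Timing of one file under one core (t1) and under C cores (tC)."""

    t1: float
    tC: float
    C: int

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.tC <= 0:
            raise ValueError("times must be positive")
        if self.C < 1:
            raise ValueError("core count must be >= 1")


def performance_gain(rec: PerfRecord) -> float:
    """PG = t1 / (C * tC).

    PG = 1 means C cores deliver exactly C-fold speedup over one core;
    PG < 1 means the per-core benefit is eroded by parallel overhead.
    """
    return rec.t1 / (rec.C * rec.tC)


@dataclass
class ExecutionResult:
    """Per-file statistics plus per-file errors (failures never cross files)."""

    stats: dict
    errors: dict


def build_work_units(path: str, passes, n_cores: int) -> list[WorkUnit]:
    """Cut one file into record-aligned work units for the given passes.

    Byte budgets are rounded down to record boundaries; the final pass
    absorbs all rounding remainders, so the units are disjoint and cover
    the file exactly.
    """
    compressed = is_gzip_path(path)
    units: list[WorkUnit] = []
    if compressed:
        with open_fastq(path) as fh:
            n_records = sum(1 for _ in parse_fastq(fh))
        bounds = _pass_bounds(n_records, passes)
        for p, (lo, hi) in enumerate(bounds):
            for c, (clo, chi) in enumerate(_chunk_bounds(lo, hi, n_cores)):
                if chi > clo:
                    units.append(
                        WorkUnit(
                            path=path,
                            pass_index=p,
                            chunk_index=c,
                            start_record=clo,
                            end_record=chi,
                            compressed=True,
                        )
                    )
        return units

    offsets = index_records(path)
    n_records = len(offsets) - 1
    size = offsets[-1]
    # Advance each pass's cumulative byte budget to the next record start.
    record_bounds = []
    rec = 0
    budget = 0
    for frac in passes[:-1]:
        budget += int(frac * size)
        while rec < n_records and offsets[rec] < budget:
            rec += 1
        record_bounds.append(rec)
    pass_edges = [0] + record_bounds + [n_records]
    for p in range(len(passes)):
        lo, hi = pass_edges[p], pass_edges[p + 1]
        for c, (clo, chi) in enumerate(_chunk_bounds(lo, hi, n_cores)):
            if chi > clo:
                units.append(
                    WorkUnit(
                        path=path,
                        pass_index=p,
                        chunk_index=c,
                        start_byte=offsets[clo],
                        end_byte=offsets[chi],
                    )
                )
    return units


def _pass_bounds(n_records: int, passes) -> list[tuple[int, int]]:
    edges = [0]
    acc = 0
    total = 0
    for frac in passes[:-1]:
        total += frac
        acc = int(total * n_records)
        edges.append(acc)
    edges.append(n_records)
    return list(zip(edges[:-1], edges[1:]))


def _chunk_bounds(lo: int, hi: int, k: int) -> list[tuple[int, int]]:
    n = hi - lo
    k = max(1, min(k, n)) if n else 1
    base, extra = divmod(n, k)
    bounds = []
    start = lo
    for i in range(k):
        end = start + base + (1 if i < extra else 0)
        bounds.append((start, end))
        start = end
    return bounds


def run_work_unit(
    unit: WorkUnit,
    q_threshold: float = DEFAULT_Q,
    offset: int = DEFAULT_PHRED_OFFSET,
    inclusive: bool = False,
) -> SegmentStats:
    """Compute statistics for one work unit (module-level: picklable)."""
    t0 = time.perf_counter()
    if unit.compressed:
        with open_fastq(unit.path) as fh:
            records = islice(
                parse_fastq(fh), unit.start_record, unit.end_record
            )
            stats = compute_segment_stats(
                records, q_threshold=q_threshold, offset=offset, inclusive=inclusive
            )
    else:
        with open(unit.path, "rb") as fh:
            fh.seek(unit.start_byte)
            blob = fh.read(unit.end_byte - unit.start_byte)
        stream = io.StringIO(blob.decode("ascii"))
        stats = compute_segment_stats(
            parse_fastq(stream), q_threshold=q_threshold, offset=offset,
            inclusive=inclusive,
        )
    logger.info(
        "unit %s pass=%d chunk=%d records=%d elapsed=%.3fs",
        unit.path, unit.pass_index, unit.chunk_index, stats.n_reads,
        time.perf_counter() - t0,
    )
    return stats


def execute_plan(
    plan: AllocationPlan,
    q_threshold: float = DEFAULT_Q,
    offset: int = DEFAULT_PHRED_OFFSET,
    inclusive: bool = False,
    workers: int = 1,
    keys: Optional[Mapping[str, object]] = None,
) -> ExecutionResult:
    """Run every iteration of the plan and fold segment results per file.

    Parameters
    ----------
    workers:
        Worker-process budget.  The result is byte-identical for any value
        >= 1 (worker-count invariance); 1 runs everything in-process.
    keys:
        Optional mapping from file path to a result key (e.g. a
        :class:`~fqstat.aggregation.UnitKey`); paths are used when absent.

    Returns
    -------
    ExecutionResult
        ``stats`` maps each key to its whole-file :class:`SegmentStats`;
        ``errors`` maps keys of failed files to the error message.
    """
    keys = dict(keys or {})
    stats: dict = {}
    errors: dict = {}
    for iteration in plan.iterations:
        # Build units per file; a file failing at indexing is isolated here.
        file_units: dict[str, list[WorkUnit]] = {}
        for spec, cores in zip(iteration.files, iteration.cores):
            key = keys.get(spec.path, spec.path)
            try:
                file_units[spec.path] = build_work_units(
                    spec.path, iteration.passes, cores
                )
            except Exception as exc:  # noqa: BLE001 - per-file isolation
                errors[key] = str(exc)
        all_units = [u for units in file_units.values() for u in units]
        results: dict[WorkUnit, SegmentStats] = {}
        failed_paths: dict[str, str] = {}
        if workers > 1 and len(all_units) > 1:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                futures = {
                    u: pool.submit(run_work_unit, u, q_threshold, offset, inclusive)
                    for u in all_units
                }
            for u, fut in futures.items():
                try:
                    results[u] = fut.result()
                except Exception as exc:  # noqa: BLE001
                    failed_paths.setdefault(u.path, str(exc))
        else:
            for u in all_units:
                try:
                    results[u] = run_work_unit(u, q_threshold, offset, inclusive)
                except Exception as exc:  # noqa: BLE001
                    failed_paths.setdefault(u.path, str(exc))
        # Deterministic assembly: fixed (path, pass, chunk) order.
        for path, units in file_units.items():
            key = keys.get(path, path)
            if path in failed_paths:
                errors[key] = failed_paths[path]
                continue
            acc = SegmentStats.empty(q_threshold)
            for u in sorted(units, key=lambda u: (u.pass_index, u.chunk_index)):
                acc = merge_stats(acc, results[u])
            stats[key] = acc
    return ExecutionResult(stats=stats, errors=errors)
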