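"""Core/memory allocation planning for batch FASTQ processing.

Given F input files, C available cores, and M bytes of memory, the planner
emits an :class:`AllocationPlan`:

* **Iterations** — if F > C, files are processed in groups of C (one core
  per file) until all are analyzed; the remainder group shares the cores.
  If F <= C, a single group holds all files and the cores are divided among
  them as evenly as possible, capped at ``max_core`` per file (beyond that
  cap, per-file core assignment costs more in overhead than it buys).
* **Passes** — if an iteration's total bytes exceed M, every file in the
  iteration is split into segments such that one pass over all files fits
  in memory exactly: each pass processes the same fraction
  ``f = M / total_bytes`` of every file, with a smaller remainder pass last.

When both cores and memory are constrained the planner prefers one core per
file with memory-driven splits over multi-core whole-file reads: splitting
costs less overhead than spreading a file across cores.

Pass fractions are exact rationals (:class:`fractions.Fraction`) computed on
byte counts — floating point would accumulate rounding error across passes
and break the "fractions sum to 1" and "planned bytes <= M" invariants.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence, Union

DEFAULT_MAX_CORE = 55


class PlanningError(ValueError):
    """Invalid resource configuration or unplannable input."""


@dataclass(frozen=True)
class ResourceSpec:
    """Available cores C, memory M (bytes), and the per-file core cap."""

    n_cores: int
    memory_bytes: int
    max_core: int = DEFAULT_MAX_CORE

    def __post_init__(self) -> None:
        if self.n_cores < 1:
            raise PlanningError("n_cores must be >= 1")
        if self.memory_bytes < 1:
            raise PlanningError("memory_bytes must be >= 1")
        if self.max_core < 1:
            raise PlanningError("max_core must be >= 1")


@dataclass(frozen=True)
class FileSpec:
    """One input file: path identifier and on-disk size in bytes.

    For gzip inputs the compressed on-disk size is used as the memory proxy
    (the decompressed size is unknown without a full scan).
    """

    path: str
    size_bytes: int

    def __post_init__(self) -> None:
        if self.size_bytes < 0:
            raise PlanningError(f"negative size for {self.path}")


@dataclass(frozen=True)
class Iteration:
    """One group of files processed together.

    ``cores[i]`` is the core count assigned to ``files[i]``; ``passes`` are
    the segment fractions applied to every file in the group.
    """

    files: tuple[FileSpec, ...]
    cores: tuple[int, ...]
    passes: tuple[Fraction, ...]

    @property
    def total_bytes(self) -> int:
        return sum(f.size_bytes for f in self.files)


@dataclass(frozen=True)
class AllocationPlan:
    iterations: tuple[Iteration, ...]
    resources: ResourceSpec

    @property
    def n_files(self) -> int:
        return sum(len(it.files) for it in self.iterations)

    def to_json(self) -> str:
        doc = {
            "resources": {
                "n_cores": self.resources.n_cores,
                "memory_bytes": self.resources.memory_bytes,
                "max_core": self.resources.max_core,
            },
            "iterations": [
                {
                    "files": [
                        {"path": f.path, "size_bytes": f.size_bytes}
                        for f in it.files
                    ],
                    "cores": list(it.cores),
                    "passes": [str(p) for p in it.passes],
                }
                for it in self.iterations
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AllocationPlan":
        doc = json.loads(text)
        res = ResourceSpec(**doc["resources"])
        its = tuple(
            Iteration(
                files=tuple(FileSpec(**f) for f in it["files"]),
                cores=tuple(it["cores"]),
                passes=tuple(Fraction(p) for p in it["passes"]),
            )
            for it in doc["iterations"]
        )
        return cls(iterations=its, resources=res)


def group_into_iterations(
    files: Sequence[FileSpec], n_cores: int
) -> list[list[FileSpec]]:
    """Partition files into iteration groups of at most ``n_cores`` files.

    With more files than cores: floor(F/C) full groups of C files, then one
    remainder group of F mod C files (omitted if empty).  Otherwise a single
    group.  Input order is preserved.
    """
    if n_cores < 1:
        raise PlanningError("n_cores must be >= 1")
    files = list(files)
    if not files:
        return []
    if len(files) <= n_cores:
        return [files]
    return [files[i : i + n_cores] for i in range(0, len(files), n_cores)]


def assign_cores(n_files: int, n_cores: int, max_core: int = DEFAULT_MAX_CORE) -> list[int]:
    """Per-file core counts for one iteration group.

    One core per file when files are not fewer than cores; otherwise the
    cores are divided as evenly as possible (counts differ by at most one),
    then capped at ``max_core``.
    """
    if n_files < 1 or n_cores < 1:
        raise PlanningError("n_files and n_cores must be >= 1")
    if n_files >= n_cores:
        return [1] * n_files
    base, extra = divmod(n_cores, n_files)
    counts = [base] * (n_files - extra) + [base + 1] * extra
    return [min(c, max_core) for c in counts]


def plan_passes(group_total_bytes: int, memory_bytes: int) -> list[Fraction]:
    """Segment fractions for one iteration group under a memory budget.

    Each pass processes the fraction ``f = min(1, M / total)`` of every file
    so that one pass over the whole group fills the available memory; a
    final remainder pass of ``1 - floor(1/f) * f`` covers what is left.
    Exact rational arithmetic; the fractions always sum to 1.
    """
    if memory_bytes <= 0:
        raise PlanningError("memory budget must be positive")
    if group_total_bytes < 1:
        raise PlanningError("group_total_bytes must be >= 1")
    f = min(Fraction(1), Fraction(memory_bytes, group_total_bytes))
    n_full = int(Fraction(1) / f)  # floor
    passes = [f] * n_full
    remainder = 1 - n_full * f
    if remainder > 0:
        passes.append(remainder)
    return passes


def build_plan(files: Sequence[FileSpec], res: ResourceSpec) -> AllocationPlan:
    """Compose grouping, core assignment, and pass planning into a full plan.

    Files are ordered lexicographically by path for determinism.  Passes are
    planned per iteration from the iteration's actual total bytes, so
    heterogeneous file sizes are handled; for uniform sizes this reduces to
    the one-fraction-per-file rule.
    """
    ordered = sorted(files, key=lambda f: f.path)
    iterations = []
    for group in group_into_iterations(ordered, res.n_cores):
        cores = assign_cores(len(group), res.n_cores, res.max_core)
        total = sum(f.size_bytes for f in group)
        passes = plan_passes(total, res.memory_bytes) if total > 0 else [Fraction(1)]
        iterations.append(
            Iteration(files=tuple(group), cores=tuple(cores), passes=tuple(passes))
        )
    return AllocationPlan(iterations=tuple(iterations), resources=res)


def plan_for_paths(
    paths: Sequence[Union[str, os.PathLike]], res: ResourceSpec
) -> AllocationPlan:
    """Build a plan from filesystem paths, using on-disk sizes."""
    files = [FileSpec(path=os.fspath(p), size_bytes=os.path.getsize(p)) for p in paths]
    return build_plan(files, res)
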