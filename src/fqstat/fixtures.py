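"""Seeded synthetic FASTQ datasets for testing and benchmarking.

Generates a dataset laid out under the tool's folder convention
(``<out_dir>/<sample>/<sample>_L<lane>_R<1|2>.fastq[.gz]``) with controlled
read counts, read lengths, and per-unit quality distributions, so every
pipeline stage is exercisable without downloading anything.

Quality model: integer Phred scores drawn by rounding a normal
``N(quality_mean, quality_sd)`` and clipping to [0, 41] — simple,
parameterized, and sufficient for outlier-injection tests.  Real-data
artifacts (per-cycle quality decay, adapter content, indel error profiles)
are deliberately not modeled.  Bases are uniform over ACGT.

Determinism: every (sample, lane, mate) unit derives its own
``numpy.random.SeedSequence`` from the dataset seed and the unit's labels,
with separate child streams for bases and qualities.  The same spec and
seed therefore reproduce byte-identical files, and regenerating one unit
with a shifted quality mean (:func:`inject_low_quality`) leaves every
other byte of the dataset untouched.  Gzip members are written with
``mtime=0`` so compressed output is byte-stable too.
"""

from __future__ import annotations

import gzip
import os
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .aggregation import UnitKey
from .scheduler import FileSpec

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MAX_PHRED = 41
PHRED_OFFSET = 33


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and distributions of a synthetic dataset.

    ``read_length`` is a fixed length or an inclusive (lo, hi) range
    sampled uniformly per read.  ``quality_overrides`` maps
    (sample, lane, mate) to a replacement quality mean for that unit.
    """

    n_samples: int = 2
    lanes_per_sample: int = 4
    paired: bool = True
    reads_per_lane: int = 500
    read_length: Union[int, tuple[int, int]] = 75
    quality_mean: float = 30.0
    quality_sd: float = 3.0
    quality_overrides: Mapping[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    seed: int = 0
    gzip_files: bool = False
    dataset: str = "raw"

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def lanes(self) -> list[str]:
        return [f"L{i + 1:03d}" for i in range(self.lanes_per_sample)]

    @property
    def mates(self) -> list[str]:
        return ["R1", "R2"] if self.paired else ["single"]


@dataclass
class Manifest:
    """The generated dataset: its spec, root directory, and unit files."""

    spec: FixtureSpec
    out_dir: str
    entries: list[tuple[UnitKey, FileSpec]]

    def path_for(self, key: UnitKey) -> str:
        for k, f in self.entries:
            if k == key:
                return f.path
        raise KeyError(key)

    @property
    def keys(self) -> dict[str, UnitKey]:
        """Mapping from file path to unit key, for driving the executor."""
        return {f.path: k for k, f in self.entries}


def _unit_seed(seed: int, sample: str, lane: str, mate: str) -> np.random.SeedSequence:
    # Label-derived entropy keeps the unit's stream independent of how many
    # other units exist, so injection touches exactly one file.
    label = f"{sample}/{lane}/{mate}".encode()
    return np.random.SeedSequence([seed, zlib.crc32(label)])


def sample_unit_records(
    spec: FixtureSpec, sample: str, lane: str, mate: str,
    quality_mean: Optional[float] = None,
):
    """Yield (name, bases, scores) tuples for one unit, deterministically."""
    mean = quality_mean
    if mean is None:
        mean = spec.quality_overrides.get((sample, lane, mate), spec.quality_mean)
    base_ss, qual_ss = _unit_seed(spec.seed, sample, lane, mate).spawn(2)
    base_rng = np.random.default_rng(base_ss)
    qual_rng = np.random.default_rng(qual_ss)
    if isinstance(spec.read_length, int):
        lengths = np.full(spec.reads_per_lane, spec.read_length)
    else:
        lo, hi = spec.read_length
        lengths = base_rng.integers(lo, hi + 1, size=spec.reads_per_lane)
    for i, n in enumerate(lengths):
        n = int(n)
        bases = BASES[base_rng.integers(0, 4, size=n)]
        scores = np.clip(
            np.rint(qual_rng.normal(mean, spec.quality_sd, size=n)), 0, MAX_PHRED
        ).astype(np.uint8)
        yield f"{sample}:{lane}:{mate}:{i}", bases, scores


def _write_unit(spec: FixtureSpec, path: Path, sample: str, lane: str, mate: str) -> int:
    chunks = []
    for name, bases, scores in sample_unit_records(spec, sample, lane, mate):
        chunks.append(b"@" + name.encode() + b"\n")
        chunks.append(bases.tobytes() + b"\n+\n")
        chunks.append((scores + PHRED_OFFSET).tobytes() + b"\n")
    payload = b"".join(chunks)
    path.parent.mkdir(parents=True, exist_ok=True)
    if spec.gzip_files:
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(payload)
    else:
        path.write_bytes(payload)
    return path.stat().st_size


def unit_filename(spec: FixtureSpec, sample: str, lane: str, mate: str) -> str:
    mate_part = "" if mate == "single" else f"_{mate}"
    ext = ".fastq.gz" if spec.gzip_files else ".fastq"
    return f"{sample}/{sample}_{lane}{mate_part}{ext}"


def generate_fixture(spec: FixtureSpec, out_dir: Union[str, os.PathLike]) -> Manifest:
    """Write the full dataset under ``out_dir`` and return its manifest."""
    out = Path(out_dir)
    entries = []
    for sample in spec.samples:
        for lane in spec.lanes:
            for mate in spec.mates:
                path = out / unit_filename(spec, sample, lane, mate)
                size = _write_unit(spec, path, sample, lane, mate)
                key = UnitKey(dataset=spec.dataset, sample=sample, mate=mate, lane=lane)
                entries.append((key, FileSpec(path=str(path), size_bytes=size)))
    return Manifest(spec=spec, out_dir=str(out), entries=entries)


def inject_low_quality(manifest: Manifest, target: UnitKey, delta: float) -> Manifest:
    """Regenerate one unit with its quality mean lowered by ``delta`` Phred.

    Only the target file changes; the same seed discipline keeps every
    other unit byte-identical.  Returns an updated manifest.
    """
    spec = manifest.spec
    found = False
    entries = []
    for key, fspec in manifest.entries:
        if key == target:
            found = True
            base_mean = spec.quality_overrides.get(
                (key.sample, key.lane, key.mate), spec.quality_mean
            )
            overrides = dict(spec.quality_overrides)
            overrides[(key.sample, key.lane, key.mate)] = base_mean - delta
            spec = replace(spec, quality_overrides=overrides)
            size = _write_unit(spec, Path(fspec.path), key.sample, key.lane, key.mate)
            fspec = FileSpec(path=fspec.path, size_bytes=size)
        entries.append((key, fspec))
    if not found:
        raise KeyError(f"unit {target} not in manifest")
    return Manifest(spec=spec, out_dir=manifest.out_dir, entries=entries)
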