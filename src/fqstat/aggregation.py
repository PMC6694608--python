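"""Lane / sample / experiment rollups and dataset comparison.

Statistics are computed per FASTQ file — one (dataset, sample, mate, lane)
unit — and rolled up by folding the mergeable accumulators:

* **lane** level: one row per file;
* **sample** level: lanes merged per (dataset, sample, mate);
* **experiment** level, computed at two resolutions over a dataset+mate:
  *lane resolution* pools every lane unit, *sample resolution* pools the
  sample-level accumulators.  The pooled tallies coincide (merging is
  associative); the resolutions differ in their dispersion summaries,
  which average each derived metric unweighted across lane units versus
  across sample units.

Paired-end mates are never merged across R1/R2: every level is computed
per mate.  When two datasets (e.g. "raw" and "trimmed") cover the same
units, per-metric percent differences are attached; relative differences
100*(B-A)/A by default, plain differences (percentage points for percent
metrics) in absolute mode.  A zero baseline makes the relative difference
undefined, reported as NA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .fastq_core import SegmentStats, merge_stats

#: Derived metric columns of a metric table, in output order.
METRICS = (
    "read_count",
    "len_min",
    "len_max",
    "mean_length",
    "mean_quality",
    "hq_bases",
    "hq_percent",
)

#: Metrics treated as integer counts in serialization.
COUNT_METRICS = ("read_count", "len_min", "len_max", "hq_bases")

LEVELS = ("lane", "sample", "experiment_lane", "experiment_sample")

#: Placeholder for the collapsed field of an aggregate row.
AGG = "-"


@dataclass(frozen=True, order=True)
class UnitKey:
    """Identity of one FASTQ file: dataset, sample, mate (R1/R2/single), lane."""

    dataset: str
    sample: str
    mate: str
    lane: str


def metric_values(stats: SegmentStats) -> dict[str, float]:
    """Derived metrics of one accumulator, keyed by metric name."""
    return {
        "read_count": stats.n_reads,
        "len_min": stats.len_min,
        "len_max": stats.len_max,
        "mean_length": stats.mean_length,
        "mean_quality": stats.mean_quality,
        "hq_bases": stats.hq_bases,
        "hq_percent": stats.hq_percent,
    }


def aggregate_sample(lane_stats: Mapping[str, SegmentStats]) -> SegmentStats:
    """Merge one sample+mate's lanes into a sample-level accumulator."""
    if not lane_stats:
        raise ValueError("aggregate_sample requires at least one lane")
    acc = None
    for lane in sorted(lane_stats):
        s = lane_stats[lane]
        acc = s if acc is None else merge_stats(acc, s)
    return acc


def aggregate_experiment(
    stats: Mapping[UnitKey, SegmentStats], resolution: str
) -> tuple[SegmentStats, dict[str, tuple[float, float]]]:
    """Pool units into an experiment-level accumulator plus dispersion.

    ``resolution`` is ``"lane"`` (units are the lane-level files) or
    ``"sample"`` (lanes are first merged per sample+mate).  Returns the
    pooled accumulator and, per derived metric, the unweighted mean and
    population standard deviation across the units at that resolution.
    """
    if not stats:
        raise ValueError("aggregate_experiment requires at least one unit")
    if resolution not in ("lane", "sample"):
        raise ValueError(f"unknown resolution {resolution!r}")
    if resolution == "lane":
        units = [stats[k] for k in sorted(stats)]
    else:
        by_sample: dict[tuple, dict[str, SegmentStats]] = {}
        for key in sorted(stats):
            by_sample.setdefault((key.dataset, key.sample, key.mate), {})[
                key.lane
            ] = stats[key]
        units = [aggregate_sample(lanes) for lanes in by_sample.values()]
    pooled = units[0]
    for s in units[1:]:
        pooled = merge_stats(pooled, s)
    dispersion = {}
    for metric in ("hq_percent", "mean_quality", "mean_length", "read_count"):
        values = np.array([metric_values(s)[metric] for s in units], dtype=float)
        dispersion[metric] = (float(values.mean()), float(values.std()))
    return pooled, dispersion


def percent_difference(a: float, b: float, mode: str = "relative") -> float:
    """Difference of dataset B relative to baseline A.

    ``relative``: 100 * (b - a) / a, NaN (rendered NA) when a == 0.
    ``absolute``: b - a (percentage points when a, b are percentages).
    """
    if mode == "absolute":
        return b - a
    if mode != "relative":
        raise ValueError(f"unknown diff mode {mode!r}")
    if a == 0 or not math.isfinite(a) or not math.isfinite(b):
        return float("nan")
    return 100.0 * (b - a) / a


def build_metric_table(stats: Mapping[UnitKey, SegmentStats]) -> pd.DataFrame:
    """Tidy per-unit metric table over all four levels.

    One row per (level, dataset, sample, mate, lane); aggregate rows carry
    ``"-"`` in the collapsed fields.  Rows are ordered by level, then
    dataset, sample, mate, lane.
    """
    if not stats:
        raise ValueError("no statistics to tabulate")
    rows = []
    for key in sorted(stats):
        rows.append(
            {"level": "lane", "dataset": key.dataset, "sample": key.sample,
             "mate": key.mate, "lane": key.lane, **metric_values(stats[key])}
        )
    by_sample: dict[tuple, dict[str, SegmentStats]] = {}
    for key in sorted(stats):
        by_sample.setdefault((key.dataset, key.sample, key.mate), {})[key.lane] = stats[key]
    for (dataset, sample, mate), lanes in by_sample.items():
        rows.append(
            {"level": "sample", "dataset": dataset, "sample": sample,
             "mate": mate, "lane": AGG, **metric_values(aggregate_sample(lanes))}
        )
    by_dm: dict[tuple, dict[UnitKey, SegmentStats]] = {}
    for key in sorted(stats):
        by_dm.setdefault((key.dataset, key.mate), {})[key] = stats[key]
    for (dataset, mate), sub in by_dm.items():
        for resolution, level in (("lane", "experiment_lane"), ("sample", "experiment_sample")):
            pooled, _ = aggregate_experiment(sub, resolution)
            rows.append(
                {"level": level, "dataset": dataset, "sample": AGG,
                 "mate": mate, "lane": AGG, **metric_values(pooled)}
            )
    df = pd.DataFrame(rows)
    df["level"] = pd.Categorical(df["level"], categories=LEVELS, ordered=True)
    return df.sort_values(
        ["level", "dataset", "sample", "mate", "lane"], kind="stable"
    ).reset_index(drop=True)


def compare_datasets(
    table: pd.DataFrame,
    dataset_a: str,
    dataset_b: str,
    mode: str = "relative",
) -> pd.DataFrame:
    """Pair two datasets' rows and attach per-metric difference columns.

    Pairing requires identical (sample, mate, lane) key sets at each level;
    unmatched rows are reported via a warning and excluded.  Output columns
    per metric m: ``m_a``, ``m_b``, ``m_diff``.
    """
    keys = ["level", "sample", "mate", "lane"]
    a = table[table["dataset"] == dataset_a].set_index(keys)
    b = table[table["dataset"] == dataset_b].set_index(keys)
    unmatched = a.index.symmetric_difference(b.index)
    if len(unmatched):
        warnings.warn(
            f"{len(unmatched)} units present in only one dataset are excluded "
            f"from comparison: {sorted(map(tuple, unmatched))[:5]}...",
            stacklevel=2,
        )
    shared = a.index.intersection(b.index)
    out = pd.DataFrame(index=shared)
    for m in METRICS:
        out[f"{m}_a"] = a.loc[shared, m]
        out[f"{m}_b"] = b.loc[shared, m]
        out[f"{m}_diff"] = [
            percent_difference(x, y, mode=mode)
            for x, y in zip(out[f"{m}_a"], out[f"{m}_b"])
        ]
    return out.reset_index().sort_values(keys, kind="stable").reset_index(drop=True)
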