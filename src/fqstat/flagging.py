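"""Z-score outlier flagging of lane- and sample-level units.

For each metric, a unit is compared against its peer group — all units of
the same dataset, mate, and level — and flagged when its absolute z-score
exceeds the cutoff (default 1.5).  Z-scores use the population standard
deviation (divisor n): the peer group is the complete population of units
in the experiment, not a sample from a larger one.  The unit's own value
is included in the group mean and deviation (no leave-one-out).

Degenerate peer groups produce no flags: with fewer than 3 units or a zero
standard deviation, the z-score is reported as undefined (NaN) and the
unit is not flagged.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_Z_CUTOFF = 1.5

#: Metrics flagged by default: one per statistic family.
FLAG_METRICS = ("read_count", "mean_length", "mean_quality", "hq_percent")

#: Minimum peer-group size for a meaningful z-score.
MIN_GROUP = 3


def zscores(values: Sequence[float]) -> np.ndarray:
    """Population z-scores of a value list; all-equal input yields all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("zscores requires at least one value")
    sd = arr.std()  # population (divisor n)
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def flag_units(
    table: pd.DataFrame,
    level: str = "lane",
    cutoff: float = DEFAULT_Z_CUTOFF,
    metrics: Sequence[str] = FLAG_METRICS,
) -> pd.DataFrame:
    """Flag outlier units of one level of a metric table.

    Parameters
    ----------
    table:
        Tidy metric table from :func:`fqstat.aggregation.build_metric_table`.
    level:
        ``"lane"`` or ``"sample"`` — the rows to test; peer groups are
        formed within (dataset, mate) at that level, per metric.
    cutoff:
        Absolute z-score above which a unit is flagged.

    Returns
    -------
    pandas.DataFrame
        One row per (unit, metric) with columns value, group_mean,
        group_sd, zscore, flagged.  ``flagged`` is True iff ``|z| > cutoff``
        and the z-score is defined.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if level not in ("lane", "sample"):
        raise ValueError(f"flagging applies at lane or sample level, not {level!r}")
    sub = table[table["level"] == level]
    rows = []
    for (dataset, mate), group in sub.groupby(["dataset", "mate"], observed=True):
        for metric in metrics:
            vals = group[metric].to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std())
            defined = len(vals) >= MIN_GROUP and sd > 0
            z = (vals - mean) / sd if defined else np.full(len(vals), np.nan)
            for i, (_, unit) in enumerate(group.iterrows()):
                rows.append(
                    {
                        "level": level,
                        "dataset": dataset,
                        "sample": unit["sample"],
                        "mate": mate,
                        "lane": unit["lane"],
                        "metric": metric,
                        "value": vals[i],
                        "group_mean": mean,
                        "group_sd": sd,
                        "zscore": z[i],
                        "flagged": bool(defined and abs(z[i]) > cutoff),
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["level", "dataset", "sample", "mate", "lane", "metric",
                 "value", "group_mean", "group_sd", "zscore", "flagged"],
    )
    return out.sort_values(
        ["dataset", "sample", "mate", "lane", "metric"], kind="stable"
    ).reset_index(drop=True)
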