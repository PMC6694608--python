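"""Report rendering: tab-delimited tables, HTML pages, and chart images.

Two HTML pages are produced — one for tables, one for graphs — alongside
byte-deterministic TSV exports of every table and one grouped bar chart
per metric saved as a standalone PNG at the configured resolution.  The
chart layout follows the tool's comparison figure: lanes on the x-axis
grouped by sample and mate, one bar per dataset on the primary y-axis,
and (with two datasets) the percent difference on a secondary y-axis.

Formatting rules for TSV: counts as integers, fractional values with two
decimals, undefined values as ``NA``, rows ordered by dataset, sample,
mate, lane.
"""

from __future__ import annotations

import html
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .aggregation import COUNT_METRICS, LEVELS, METRICS


@dataclass(frozen=True)
class ReportConfig:
    out_dir: str
    dpi: int = 300
    diff_mode: str = "relative"
    title: str = "FASTQ quality assessment"

    def __post_init__(self) -> None:
        if self.dpi < 72:
            raise ValueError("dpi must be >= 72")


_KEY_COLS = ("level", "dataset", "sample", "mate", "lane", "metric")


def _format_cell(col: str, value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    base = col.rsplit("_", 1)[0] if col.endswith(("_a", "_b")) else col
    if base in COUNT_METRICS and not col.endswith("_diff"):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(value)
    if isinstance(value, (float, np.floating)):
        return f"{value:.2f}"
    return str(value)


def write_tsv(table: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    """Serialize a metric/flag table to tab-delimited text, deterministically."""
    if table.empty:
        raise ValueError("refusing to write an empty table")
    sort_cols = [c for c in ("level", "dataset", "sample", "mate", "lane", "metric")
                 if c in table.columns]
    df = table.sort_values(sort_cols, kind="stable") if sort_cols else table
    lines = ["\t".join(df.columns)]
    for _, row in df.iterrows():
        lines.append("\t".join(_format_cell(c, row[c]) for c in df.columns))
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")


def read_tsv(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Parse a TSV written by :func:`write_tsv` (NA becomes NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def _html_table(df: pd.DataFrame, flagged_rows: Optional[set] = None) -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    body = []
    for idx, row in df.iterrows():
        cls = ' class="flagged"' if flagged_rows and idx in flagged_rows else ""
        cells = "".join(
            f"<td>{html.escape(_format_cell(c, row[c]))}</td>" for c in df.columns
        )
        body.append(f"<tr{cls}>{cells}</tr>")
    return (
        f"<table><thead><tr>{head}</tr></thead>"
        f"<tbody>{''.join(body)}</tbody></table>"
    )


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 2em; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; text-align: right; }}
th {{ background: #eee; }}
tr.flagged {{ background: #fdd; }}
h2 {{ margin-top: 2em; }}
img {{ max-width: 100%; }}
</style></head><body>
<h1>{title}</h1>
{content}
</body></html>
"""


def render_report(
    metrics: pd.DataFrame,
    flags: pd.DataFrame,
    config: ReportConfig,
    comparison: Optional[pd.DataFrame] = None,
) -> dict[str, list[str]]:
    """Write the tables page, graphs page, TSV exports, and chart images.

    Parameters
    ----------
    metrics:
        Tidy metric table (all levels, one or two datasets).
    flags:
        Flag table; flagged units are highlighted in the HTML tables.
    comparison:
        Optional paired-dataset table; adds difference markers on a
        secondary axis to every chart.

    Returns a mapping from artifact kind (``html``, ``tsv``, ``png``) to
    the files written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"html": [], "tsv": [], "png": []}

    flagged_units = {
        (r["dataset"], r["sample"], r["mate"], r["lane"])
        for _, r in flags.iterrows()
        if r["flagged"]
    }

    sections = []
    for level in LEVELS:
        sub = metrics[metrics["level"] == level].reset_index(drop=True)
        if sub.empty:
            continue
        tsv_path = out / f"fqstat_metrics_{level}.tsv"
        write_tsv(sub, tsv_path)
        written["tsv"].append(str(tsv_path))
        marked = {
            i for i, r in sub.iterrows()
            if (r["dataset"], r["sample"], r["mate"], r["lane"]) in flagged_units
        }
        sections.append(f"<h2>{html.escape(level)} level</h2>")
        sections.append(_html_table(sub, marked))
    if not flags.empty:
        for level in flags["level"].unique():
            fsub = flags[flags["level"] == level].reset_index(drop=True)
            tsv_path = out / f"fqstat_flags_{level}.tsv"
            write_tsv(fsub, tsv_path)
            written["tsv"].append(str(tsv_path))
        sections.append("<h2>Flags</h2>")
        sections.append(_html_table(flags.reset_index(drop=True)))
    if comparison is not None and not comparison.empty:
        tsv_path = out / "fqstat_comparison.tsv"
        write_tsv(comparison, tsv_path)
        written["tsv"].append(str(tsv_path))
        sections.append("<h2>Dataset comparison</h2>")
        sections.append(_html_table(comparison.reset_index(drop=True)))

    tables_path = out / "fqstat_tables.html"
    tables_path.write_text(
        _PAGE.format(title=html.escape(config.title), content="\n".join(sections)),
        encoding="utf-8",
    )
    written["html"].append(str(tables_path))

    img_tags = []
    for metric in METRICS:
        png = out / f"fqstat_{metric}.png"
        _plot_metric(metrics, metric, comparison, config, png)
        written["png"].append(str(png))
        img_tags.append(f"<h2>{html.escape(metric)}</h2>")
        img_tags.append(f'<img src="{png.name}" alt="{html.escape(metric)}">')
    graphs_path = out / "fqstat_graphs.html"
    graphs_path.write_text(
        _PAGE.format(title=html.escape(config.title), content="\n".join(img_tags)),
        encoding="utf-8",
    )
    written["html"].append(str(graphs_path))
    return written


def _plot_metric(
    metrics: pd.DataFrame,
    metric: str,
    comparison: Optional[pd.DataFrame],
    config: ReportConfig,
    path: Path,
) -> None:
    lanes = metrics[metrics["level"] == "lane"]
    datasets = sorted(lanes["dataset"].unique())
    groups = (
        lanes[["sample", "mate", "lane"]]
        .drop_duplicates()
        .sort_values(["sample", "mate", "lane"])
        .reset_index(drop=True)
    )
    x = np.arange(len(groups))
    width = 0.8 / max(len(datasets), 1)
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(groups)), 4))
    for d, dataset in enumerate(datasets):
        sub = lanes[lanes["dataset"] == dataset].set_index(["sample", "mate", "lane"])
        vals = [
            sub.loc[(r["sample"], r["mate"], r["lane"]), metric]
            if (r["sample"], r["mate"], r["lane"]) in sub.index else np.nan
            for _, r in groups.iterrows()
        ]
        ax.bar(x + (d - (len(datasets) - 1) / 2) * width, vals, width, label=dataset)
    ax.set_xticks(x)
    ax.set_xticklabels(
        [f"{r['sample']}\n{r['mate']}\n{r['lane']}" for _, r in groups.iterrows()],
        fontsize=7,
    )
    ax.set_ylabel(metric)
    ax.set_title(metric)
    if comparison is not None and not comparison.empty:
        comp = comparison[comparison["level"] == "lane"].set_index(
            ["sample", "mate", "lane"]
        )
        diffs = [
            comp.loc[(r["sample"], r["mate"], r["lane"]), f"{metric}_diff"]
            if (r["sample"], r["mate"], r["lane"]) in comp.index else np.nan
            for _, r in groups.iterrows()
        ]
        ax2 = ax.twinx()
        ax2.plot(x, diffs, "ko--", markersize=4, label="% difference")
        unit = "%" if config.diff_mode == "relative" else "Δ"
        ax2.set_ylabel(f"difference ({unit})")
    if len(datasets) > 1 or comparison is not None:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=config.dpi)
    plt.close(fig)
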