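"""Tabular report assembly: per-sample QC tables, grouped medians,
pairwise metric correlations, and per-condition peak tallies.

The QC table layout mirrors a per-sample supplementary table: sample id
and design columns (buffer, temperature, enzyme, fixation) first, metric
columns after.  The condition-peak layout is BED3 plus four columns of
comma-joined condition descriptors (fixation, buffer, temperature,
enzyme); the i-th tokens across the four columns jointly name the i-th
condition a peak was detected in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import QcReport

METRIC_COLUMNS = (
    "frip", "tss_enrichment", "subnucleosomal_score",
    "pct_mito", "estimated_complexity",
)

__all__ = [
    "qc_table",
    "summarize_qc_table",
    "qc_correlations",
    "tally_condition_peaks",
    "condition_peak_summary",
]


def qc_table(reports: list[tuple[dict, QcReport]]) -> pd.DataFrame:
    """Assemble per-sample QC rows; design keys (sample, buffer, ...) first."""
    rows = []
    for design, report in reports:
        row = dict(design)
        row.update(report.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_qc_table(
    table: pd.DataFrame,
    group_cols: list[str],
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Per-group medians of the metric columns (missing values excluded)."""
    present = [m for m in metrics if m in table.columns]
    return (
        table.groupby(group_cols, dropna=False)[present]
        .median()
        .reset_index()
    )


def qc_correlations(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Pairwise Pearson correlations among the metrics."""
    present = [m for m in metrics if m in table.columns]
    sub = table[present].astype(float)
    return sub.corr(method="pearson")


def tally_condition_peaks(path_or_df) -> pd.Series:
    """Per-condition peak counts from a condition-peak table file.

    Accepts a path to a BED3+4 file (columns 4-7: comma-joined fixation,
    buffer, temperature, enzyme tokens) or an equivalent DataFrame whose
    columns are chrom/start/end/fixation/buffer/temperature/enzyme.
    Returns counts indexed by the joined condition descriptor
    ``fixation|buffer|temperature|enzyme``.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(
            path_or_df, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "fixation", "buffer",
                   "temperature", "enzyme"],
            dtype=str,
        )
    counts: dict[str, int] = {}
    cols = ["fixation", "buffer", "temperature", "enzyme"]
    for _, row in df.iterrows():
        tokens = [str(row[c]).split(",") for c in cols]
        lengths = {len(t) for t in tokens}
        if len(lengths) != 1:
            raise ValueError(
                "condition descriptor columns disagree in token count at "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        for combo in {tuple(t[i] for t in tokens) for i in range(lengths.pop())}:
            key = "|".join(combo)
            counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, name="n_peaks").sort_index()


def condition_peak_summary(
    counts: pd.Series, fixation_token_index: int = 0
) -> pd.DataFrame:
    """Median/max/min peak counts stratified by the fixation token."""
    fixation = [key.split("|")[fixation_token_index] for key in counts.index]
    frame = pd.DataFrame({"fixation": fixation, "n_peaks": counts.to_numpy()})
    return (
        frame.groupby("fixation")["n_peaks"]
        .agg(["median", "max", "min"])
        .reset_index()
    )
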