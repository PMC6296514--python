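"""Collapse run-level metrics to subject x modality values.

Two steps: arithmetic averaging of the (typically two) runs within each
subject x modality x scheme cell, then outlier control that replaces
values beyond mean +/- k*SD of their column with the boundary value
(winsorization).  Boundary statistics are computed once, from the
pre-replacement distribution, with the sample (n-1) SD.
"""

from __future__ import annotations

import logging

import pandas as pd

from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

KEY_COLS = ["subject_id", "modality", "scheme"]


def average_runs(run_metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean across runs per (subject, modality, scheme) per metric.

    Every key must carry the same number of runs; a missing run is a hard
    error because a subject-level mean of unequal run counts would weight
    subjects inconsistently.
    """
    df = run_metrics.copy()
    counts = df.groupby(KEY_COLS, sort=True)["run_index"].count()
    if counts.nunique() > 1:
        expected = counts.max()
        bad = counts[counts != expected]
        raise ValueError(f"missing runs for keys: {list(bad.index)}")
    out = (
        df.groupby(KEY_COLS, sort=True)[list(METRIC_NAMES)]
        .mean()
        .reset_index()
    )
    out["stage"] = "run_averaged"
    return out


def winsorize(
    values: pd.DataFrame,
    k: float = 2.0,
    group_cols: tuple[str, ...] = ("modality", "scheme"),
) -> pd.DataFrame:
    """Replace values beyond mean +/- k*SD with the boundary value.

    Grouping is per metric column within each ``group_cols`` cell across
    subjects (default: each metric x modality x scheme column, i.e. each
    column that enters the regression).  A zero-SD group is returned
    unchanged.
    """
    df = values.copy()
    df[list(METRIC_NAMES)] = df[list(METRIC_NAMES)].astype(float)
    group_cols = list(group_cols)
    for metric in METRIC_NAMES:
        for key, idx in df.groupby(group_cols, sort=True).groups.items():
            col = df.loc[idx, metric]
            if len(col) < 3:
                raise ValueError(
                    f"winsorize needs >= 3 subjects per group; got {len(col)} for {key}"
                )
            mean, sd = col.mean(), col.std(ddof=1)
            if sd == 0:
                logger.info("winsorize: zero SD for %s %s; values unchanged", metric, key)
                continue
            lo, hi = mean - k * sd, mean + k * sd
            n_out = int(((col < lo) | (col > hi)).sum())
            if n_out:
                logger.info("winsorize: %d replacement(s) for %s %s", n_out, metric, key)
            df.loc[idx, metric] = col.clip(lo, hi)
    df["stage"] = "winsorized"
    return df
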