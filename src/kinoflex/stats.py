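"""Welch's unequal-variance t-test and the active-vs-inactive comparison report.

Welch's test generalizes Student's t to samples with unequal variances
and/or sizes — exactly the situation when comparing pocket volumes or
connection weights between active and inactive kinase panels of different
sizes. Two-sided p-values throughout; sample variances use the n-1
denominator; no multiple-testing correction by default (an optional
Bonferroni flag is available), mirroring how raw per-pocket p-values are
conventionally reported in this analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["WelchResult", "welch_t_test", "compare_groups"]


@dataclass(frozen=True)
class WelchResult:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p and group stats."""

    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided Welch unequal-variance t-test of mean(x) = mean(y).

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y), with real-valued
    Welch-Satterthwaite degrees of freedom and the p-value from Student's t.

    Raises
    ------
    ValueError
        If either sample has fewer than 2 values, or both samples have zero
        variance with equal means (t undefined: 0/0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            raise ValueError("both samples constant and equal: t is undefined (0/0)")
        raise ValueError("both samples have zero variance: t is unbounded")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        n_x=len(x),
        n_y=len(y),
    )


def compare_groups(
    values: pd.DataFrame,
    threshold: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-pocket, per-metric Welch comparison of active vs inactive systems.

    ``values`` is a tidy table with columns ``system, label, pocket, metric,
    value`` (labels ``active``/``inactive``). Returns one row per (pocket,
    metric) with t, df, p, group means/sizes and a significance flag at
    ``threshold`` (optionally Bonferroni-divided by the number of tests).
    A pocket missing one class entirely is reported as untestable rather
    than silently dropped.
    """
    required = {"system", "label", "pocket", "metric", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"values table missing columns: {sorted(missing)}")

    groups = list(values.groupby(["pocket", "metric"], sort=True))
    alpha = threshold / len(groups) if bonferroni else threshold
    rows = []
    for (pocket, metric), g in groups:
        x = g.loc[g["label"] == "active", "value"].to_numpy(dtype=float)
        y = g.loc[g["label"] == "inactive", "value"].to_numpy(dtype=float)
        row = {"pocket": pocket, "metric": metric, "n_active": len(x), "n_inactive": len(y)}
        try:
            res = welch_t_test(x, y)
            row.update(
                t=res.t, df=res.df, p=res.p,
                mean_active=res.mean_x, mean_inactive=res.mean_y,
                significant=bool(res.p < alpha), testable=True,
            )
        except ValueError as err:
            row.update(
                t=np.nan, df=np.nan, p=np.nan,
                mean_active=float(x.mean()) if len(x) else np.nan,
                mean_inactive=float(y.mean()) if len(y) else np.nan,
                significant=False, testable=False, reason=str(err),
            )
        rows.append(row)
    return pd.DataFrame(rows)
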