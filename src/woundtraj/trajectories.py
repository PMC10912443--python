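"""Functional-category and cell-type trajectories over days post-injury.

Per-sample summed normalized expression of each functional category (and each
inferred cell-type proportion) is related to time within each of the four
wound groups via Spearman's rank correlation and an ordinary least-squares
linear fit.  Each (feature, group) trajectory is classified as

    positive  if rho >  0.1
    negative  if rho < -0.1
    flat      otherwise (boundary values inclusive to flat),

so the three classes partition [-1, 1].
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import WOUND_GROUPS, GeneSetCatalog

RHO_POSITIVE = 0.1
RHO_NEGATIVE = -0.1

TRAJECTORY_COLUMNS = ("feature", "kind", "group", "rho", "slope",
                      "intercept", "n_samples", "trend")


def sum_category_expression(norm_values: pd.DataFrame,
                            catalog: GeneSetCatalog) -> pd.DataFrame:
    """Category x sample matrix of summed normalized expression.

    Each entry is the sum of normalized counts over the category's genes that
    are present in the matrix; a gene in several categories contributes to
    each.  Categories with no overlapping gene are dropped with a warning.
    """
    rows = {}
    dropped = []
    for name, members in catalog.items():
        present = norm_values.index.intersection(list(members))
        if len(present) == 0:
            dropped.append(name)
            continue
        if len(present) < len(members):
            missing = set(members) - set(present)
            warnings.warn(
                f"category {name!r}: {len(missing)} gene(s) absent from the "
                "matrix", stacklevel=2)
        rows[name] = norm_values.loc[present].sum(axis=0)
    if dropped:
        warnings.warn(
            f"dropped categories with no genes in the matrix: {dropped}",
            stacklevel=2)
    return pd.DataFrame(rows).T


def group_spearman(values: pd.Series, meta: pd.DataFrame,
                   group: str) -> tuple[float, int]:
    """Spearman rho (average-rank ties) of value vs days post-injury in a group.

    Returns (rho, n).  rho is NaN when the group has fewer than 3 samples or
    either variable is constant.
    """
    ids = meta.index[meta["group"] == group]
    ids = ids.intersection(values.index)
    v = values.loc[ids].to_numpy(dtype=float)
    d = meta.loc[ids, "days_post_injury"].to_numpy(dtype=float)
    n = len(ids)
    if n < 3 or np.ptp(v) == 0 or np.ptp(d) == 0:
        return float("nan"), n
    rho = stats.spearmanr(v, d).statistic
    return float(rho), n


def fit_linear_trend(values: np.ndarray,
                     days: np.ndarray) -> tuple[float, float]:
    """OLS slope and intercept of value on day; NaN on < 2 distinct days."""
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=float)
    if len(np.unique(days)) < 2:
        return float("nan"), float("nan")
    slope, intercept, *_ = stats.linregress(days, values)
    return float(slope), float(intercept)


def classify_rho(rho: float) -> Optional[str]:
    """Trend class for one rho; None when rho is undefined."""
    if np.isnan(rho):
        return None
    if rho > RHO_POSITIVE:
        return "positive"
    if rho < RHO_NEGATIVE:
        return "negative"
    return "flat"


def build_trajectory_table(features: pd.DataFrame, meta: pd.DataFrame,
                           kind: str,
                           groups: tuple[str, ...] = WOUND_GROUPS,
                           ) -> pd.DataFrame:
    """One row per (feature, wound group): rho, OLS fit, trend class.

    ``features`` is a feature x sample matrix (summed category expression or
    cell-type proportions, transposed to features x samples); ``kind`` tags
    rows as ``category``, ``cell_type`` or ``m1_m2_ratio``.
    """
    rows = []
    for group in groups:
        ids = meta.index[meta["group"] == group].intersection(features.columns)
        days = meta.loc[ids, "days_post_injury"].to_numpy(dtype=float)
        for feat in features.index:
            series = features.loc[feat, ids].astype(float)
            ok = series.notna()
            rho, n = group_spearman(series[ok], meta, group)
            if ok.sum() >= 2:
                slope, intercept = fit_linear_trend(
                    series[ok].to_numpy(), days[ok.to_numpy()])
            else:
                slope, intercept = float("nan"), float("nan")
            rows.append({
                "feature": feat, "kind": kind, "group": group,
                "rho": rho, "slope": slope, "intercept": intercept,
                "n_samples": n, "trend": classify_rho(rho)})
    return pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))


def classify_trends(table: pd.DataFrame) -> pd.DataFrame:
    """Tally of positive/flat/negative trends per (kind, group).

    Features with undefined rho are excluded from the tally and counted in a
    ``missing`` column.
    """
    rows = []
    for (kind, group), sub in table.groupby(["kind", "group"], sort=True):
        counts = sub["trend"].value_counts()
        rows.append({
            "kind": kind, "group": group,
            "positive": int(counts.get("positive", 0)),
            "flat": int(counts.get("flat", 0)),
            "negative": int(counts.get("negative", 0)),
            "missing": int(sub["trend"].isna().sum())})
    return pd.DataFrame(rows)
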