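"""PCA of the Spearman-rho matrix across wound groups.

The trajectory table (categories, cell types, M1/M2 ratio) is pivoted into a
feature x group matrix of Spearman rho values.  PCA is run with the four wound
groups as observations and the features as variables (a biplot view: group
points, feature arrows), by centered SVD; unit scaling is optional since all
entries already share the rho scale.  Per-variable contributions to a
component are squared loadings expressed as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import WOUND_GROUPS

_KIND_ORDER = {"category": 0, "cell_type": 1, "m1_m2_ratio": 2}


@dataclass
class RhoMatrix:
    """Feature x wound-group matrix of Spearman rho values."""

    values: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


@dataclass
class PcaResult:
    scores: pd.DataFrame              # observations x components
    loadings: pd.DataFrame            # variables x components
    variance_explained: pd.Series     # percent per component
    contributions: pd.DataFrame       # variables x components, percent


def assemble_rho_matrix(table: pd.DataFrame,
                        groups: tuple[str, ...] = WOUND_GROUPS) -> RhoMatrix:
    """Pivot a trajectory table into features x groups of rho values.

    Features missing a finite rho in any group are excluded from PCA and
    listed.  Feature order is stable: categories first, then cell types, then
    the macrophage ratio, alphabetical within kind.
    """
    present = set(table["group"])
    missing_groups = [g for g in groups if g not in present]
    if missing_groups:
        raise ValueError(f"trajectory table lacks group(s): {missing_groups}")
    tab = table.copy()
    tab["_order"] = tab["kind"].map(_KIND_ORDER).fillna(99)
    order = (tab.sort_values(["_order", "feature"])["feature"]
             .drop_duplicates().tolist())
    wide = tab.pivot_table(index="feature", columns="group", values="rho",
                           aggfunc="first").reindex(index=order,
                                                    columns=list(groups))
    complete = wide.notna().all(axis=1)
    excluded = list(wide.index[~complete])
    return RhoMatrix(values=wide.loc[complete], excluded=excluded)


def pca(matrix: RhoMatrix | pd.DataFrame, observations: str = "groups",
        scale: bool = False) -> PcaResult:
    """Centered (optionally unit-scaled) PCA by SVD.

    ``observations="groups"`` treats wound groups as rows and features as
    variables (the default biplot orientation); ``"features"`` transposes.
    Component signs are stabilized so the largest-|loading| variable of each
    component is positive, making repeated runs identical.
    """
    values = matrix.values if isinstance(matrix, RhoMatrix) else matrix
    if observations == "groups":
        data = values.T  # rows = groups
    elif observations == "features":
        data = values
    else:
        raise ValueError(f"unknown observations mode {observations!r}")
    if data.isna().any().any():
        raise ValueError("PCA input contains missing entries")
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = data.columns[sd == 0][0]
            raise ValueError(f"zero-variance variable with scaling on: {bad!r}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = len(s)
    # Sign stabilization: largest-|loading| variable positive per component.
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=data.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=data.columns, columns=comp)
    var = s ** 2
    var_pct = pd.Series(
        100.0 * var / var.sum() if var.sum() > 0 else np.zeros(k),
        index=comp, name="variance_explained_pct")
    sq = loadings.to_numpy() ** 2
    col = sq.sum(axis=0)
    contributions = pd.DataFrame(
        100.0 * sq / np.where(col == 0, 1.0, col),
        index=loadings.index, columns=comp)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_explained=var_pct, contributions=contributions)


def group_separation_report(result: PcaResult,
                            n_components: int = 2) -> dict:
    """Which pair of groups each leading component separates most.

    For each component, reports the pair of observations with the largest
    score gap (ties broken by name order); a component with identical scores
    reports no separation.
    """
    report: dict[str, dict] = {}
    obs = list(result.scores.index)
    for comp in result.scores.columns[:n_components]:
        sc = result.scores[comp]
        best = None
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                gap = abs(sc.iloc[i] - sc.iloc[j])
                pair = tuple(sorted((str(obs[i]), str(obs[j]))))
                if best is None or gap > best[0] + 1e-12:
                    best = (gap, pair)
        gap, pair = best
        if gap < 1e-12:
            report[comp] = {"separates": None, "gap": 0.0}
        else:
            report[comp] = {"separates": list(pair), "gap": float(gap)}
    return report
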