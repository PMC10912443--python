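"""Dynamic network analysis (DyNA).

For each stratum (wound outcome by default) and each window of two consecutive
time periods (day pairs d4-5, d5-6, ... or adjacent temporal-grouping pairs),
a gene graph is built whose edges connect gene pairs with |Pearson r| at or
above a stringency threshold (default 0.99).  Each network is summarized by
the complexity score

    complexity = (N_1 + N_2 + ... + N_n) / (n - 1) = 2|E| / (n - 1),

where N_i is the number of connections of gene i and n the total number of
genes analyzed (isolated and zero-variance genes included, keeping n stable
across windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import DEFAULT_TIME_BINS, TimeBin, assign_time_bins


@dataclass
class DynaConfig:
    stringency: float = 0.99
    window_scheme: str = "consecutive_days"  # or "consecutive_bins"
    min_samples_per_window: int = 3
    stratify_by: str = "outcome"

    def __post_init__(self) -> None:
        if not 0.0 < self.stringency <= 1.0:
            raise ValueError("stringency must be in (0, 1]")
        if self.min_samples_per_window < 3:
            # r from 2 points is always +/-1; such windows are degenerate.
            raise ValueError("min_samples_per_window must be >= 3")
        if self.window_scheme not in ("consecutive_days", "consecutive_bins"):
            raise ValueError(f"unknown window scheme {self.window_scheme!r}")


@dataclass
class Window:
    label: str
    stratum: str
    sample_ids: list[str]
    skipped: bool = False


@dataclass
class CorrelationNetwork:
    window: str
    stratum: str
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (gene_a, gene_b, r)
    complexity: float
    n_samples: int
    degenerate_nodes: list[str] = field(default_factory=list)


def build_windows(meta: pd.DataFrame, config: DynaConfig,
                  bins: Sequence[TimeBin] = DEFAULT_TIME_BINS,
                  ) -> dict[str, list[Window]]:
    """Per-stratum ordered windows over two consecutive periods.

    ``consecutive_days``: one window per adjacent observed-day pair (d, d+1)
    spanning the stratum's day range.  ``consecutive_bins``: one window per
    adjacent pair of the default temporal groupings.  Windows with fewer than
    ``min_samples_per_window`` samples are flagged skipped (reported missing,
    not zero, in the complexity trajectory).
    """
    out: dict[str, list[Window]] = {}
    for stratum, sub in meta.groupby(config.stratify_by, sort=True):
        windows: list[Window] = []
        if config.window_scheme == "consecutive_days":
            days = sub["days_post_injury"].astype(int)
            lo, hi = int(days.min()), int(days.max())
            for d in range(lo, hi):
                ids = list(sub.loc[days.isin((d, d + 1)), "sample_id"])
                windows.append(Window(
                    label=f"d{d}-{d + 1}", stratum=str(stratum),
                    sample_ids=ids,
                    skipped=len(ids) < config.min_samples_per_window))
        else:
            bin_of = assign_time_bins(sub, bins)
            for b1, b2 in zip(bins, bins[1:]):
                ids = list(sub.loc[bin_of.isin((b1.label, b2.label)).to_numpy(),
                                   "sample_id"])
                windows.append(Window(
                    label=f"{b1.label},{b2.label}", stratum=str(stratum),
                    sample_ids=ids,
                    skipped=len(ids) < config.min_samples_per_window))
        if not any(not w.skipped for w in windows):
            warnings.warn(
                f"stratum {stratum!r} has no window with at least "
                f"{config.min_samples_per_window} samples", stacklevel=2)
        out[str(stratum)] = windows
    return out


def correlation_network(expr: pd.DataFrame, config: DynaConfig,
                        window: str = "", stratum: str = "",
                        ) -> CorrelationNetwork:
    """Thresholded Pearson-correlation graph for one window.

    ``expr`` is genes x samples restricted to the down-selected genes and the
    window's samples.  Genes with zero variance within the window cannot form
    edges (r undefined) but remain in the node set, so n — the complexity
    denominator — is the full number of genes analyzed.
    """
    genes = list(expr.index)
    if len(genes) < 2:
        raise ValueError("correlation network needs at least 2 genes")
    n_samples = expr.shape[1]
    if n_samples < config.min_samples_per_window:
        raise ValueError(
            f"window has {n_samples} samples, fewer than the minimum "
            f"{config.min_samples_per_window}")
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    live = sd > 0
    degenerate = [g for g, ok in zip(genes, live) if not ok]
    edges: list[tuple[str, str, float]] = []
    if live.sum() >= 2:
        r = np.corrcoef(arr[live])
        live_genes = [g for g, ok in zip(genes, live) if ok]
        iu, ju = np.triu_indices(len(live_genes), k=1)
        hit = np.abs(r[iu, ju]) >= config.stringency
        edges = [(live_genes[i], live_genes[j], float(r[i, j]))
                 for i, j in zip(iu[hit], ju[hit])]
    n = len(genes)
    complexity = 2.0 * len(edges) / (n - 1)
    return CorrelationNetwork(window=window, stratum=stratum, nodes=genes,
                              edges=edges, complexity=complexity,
                              n_samples=n_samples,
                              degenerate_nodes=degenerate)


def dyna_networks(expr: pd.DataFrame, meta: pd.DataFrame,
                  config: DynaConfig,
                  bins: Sequence[TimeBin] = DEFAULT_TIME_BINS,
                  ) -> dict[str, list[Optional[CorrelationNetwork]]]:
    """Build every window's network per stratum; skipped windows yield None."""
    windows = build_windows(meta, config, bins)
    out: dict[str, list[Optional[CorrelationNetwork]]] = {}
    for stratum, wins in windows.items():
        nets: list[Optional[CorrelationNetwork]] = []
        for w in wins:
            if w.skipped:
                nets.append(None)
            else:
                nets.append(correlation_network(
                    expr.loc[:, w.sample_ids], config,
                    window=w.label, stratum=stratum))
        out[stratum] = nets
    return out


def complexity_trajectory(
        networks: dict[str, list[Optional[CorrelationNetwork]]],
        windows: dict[str, list[Window]],
        ) -> pd.DataFrame:
    """Tidy per-stratum complexity series; skipped windows are NaN."""
    rows = []
    for stratum, nets in networks.items():
        for w, net in zip(windows[stratum], nets):
            rows.append({
                "stratum": stratum,
                "window": w.label,
                "n_samples": len(w.sample_ids),
                "complexity": np.nan if net is None else net.complexity,
                "n_edges": np.nan if net is None else len(net.edges),
            })
    return pd.DataFrame(rows)


def to_graphml(net: CorrelationNetwork, path: str | Path) -> None:
    g = nx.Graph(window=net.window, stratum=net.stratum,
                 complexity=net.complexity)
    g.add_nodes_from(net.nodes)
    for a, b, r in net.edges:
        g.add_edge(a, b, r=r, sign=1 if r >= 0 else -1)
    nx.write_graphml(g, str(path))


def to_edge_list(net: CorrelationNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.edges, columns=["gene_a", "gene_b", "r"])
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
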