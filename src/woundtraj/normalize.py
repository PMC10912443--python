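"""Normalizations the downstream stages consume.

Implements the median-of-ratios size-factor estimator (the "ratio" method used
for normalized read counts), transcripts-per-million (TPM), median-centering
for cross-platform comparison, and the high-expression gene down-selection
used before network construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountsMatrix


@dataclass
class NormalizedMatrix:
    """Counts divided by per-sample size factors, plus the factors."""

    values: pd.DataFrame
    size_factors: pd.Series


def size_factors_median_of_ratios(counts: CountsMatrix,
                                  positive_only: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample s, factor_s = median over genes g of
    count_gs / geomean_g, where geomean_g is the geometric mean of gene g
    across samples, taken over genes with all-positive counts.

    With ``positive_only`` the per-gene geometric mean is computed over the
    samples where the gene is positive (a fallback for sparse matrices where
    no gene is positive everywhere); off by default so sparse data fail
    loudly.
    """
    arr = counts.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    # The median is taken on the log scale (an even-count median averages the
    # two middle log-ratios, i.e. interpolates geometrically), matching the
    # reference "ratio" estimator.
    if positive_only:
        finite = np.isfinite(logs)
        usable = finite.any(axis=1)
        log_geomean = np.full(arr.shape[0], -np.inf)
        log_geomean[usable] = np.array(
            [logs[i, finite[i]].mean() for i in np.nonzero(usable)[0]])
        log_ratios = logs[usable] - log_geomean[usable, None]
        log_ratios[~finite[usable]] = np.nan  # zero counts: drop from median
        factors = np.exp(np.nanmedian(log_ratios, axis=0))
    else:
        usable = np.isfinite(logs).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has positive counts in every sample; re-run with "
                "positive_only=True to use the positive-counts fallback")
        log_geomean = logs[usable].mean(axis=1)
        factors = np.exp(np.median(logs[usable] - log_geomean[:, None],
                                   axis=0))
    if not (np.isfinite(factors).all() and (factors > 0).all()):
        raise ValueError("size factor estimation produced a non-positive factor")
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def normalize_counts(counts: CountsMatrix,
                     positive_only: bool = False) -> NormalizedMatrix:
    """Counts scaled by median-of-ratios size factors."""
    factors = size_factors_median_of_ratios(counts, positive_only=positive_only)
    values = counts.values.astype(float).div(factors, axis=1)
    return NormalizedMatrix(values=values, size_factors=factors)


def tpm(counts: CountsMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized within-sample abundances.

    rate_gs = count_gs / length_g; tpm_gs = 1e6 * rate_gs / sum_g rate_gs.
    Columns sum to 1e6 whenever the sample has any nonzero gene; an all-zero
    sample yields an all-zero column with a warning.
    """
    if counts.gene_lengths is None:
        raise ValueError("TPM requires gene lengths")
    rate = counts.values.to_numpy(dtype=float) / \
        counts.gene_lengths.to_numpy()[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample(s) yield all-zero TPM columns",
            stacklevel=2)
    safe = np.where(zero, 1.0, totals)
    out = 1e6 * rate / safe
    out[:, zero] = 0.0
    return pd.DataFrame(out, index=counts.values.index,
                        columns=counts.values.columns)


def median_center(matrix: pd.DataFrame,
                  axes: Sequence[str] = ("genes", "samples")) -> pd.DataFrame:
    """Subtract medians along the given axes, applied in order.

    ``genes`` centers each gene (row) across samples; ``samples`` centers each
    sample (column) across genes.  The median along the last axis applied is
    exactly zero afterwards.  Because the operations do not commute in
    general, the order is part of the output's provenance.
    """
    if not axes:
        raise ValueError("axes must be non-empty")
    out = matrix.astype(float).copy()
    for axis in axes:
        if axis == "genes":
            out = out.sub(out.median(axis=1), axis=0)
        elif axis == "samples":
            out = out.sub(out.median(axis=0), axis=1)
        else:
            raise ValueError(f"unknown axis {axis!r}")
    return out


def downselect_genes(tpm_matrix: pd.DataFrame,
                     min_mean: float = 1000.0,
                     require_all_positive: bool = True) -> list[str]:
    """Genes with mean TPM >= ``min_mean`` (and every value > 0 when flagged).

    This reproduces the unbiased pre-network reduction: transcripts with
    values > 0 in every sample and a mean TPM of at least 1000.
    """
    mean_ok = tpm_matrix.mean(axis=1) >= min_mean
    keep = mean_ok
    if require_all_positive:
        keep = keep & (tpm_matrix > 0).all(axis=1)
    selected = list(tpm_matrix.index[keep])
    if not selected:
        warnings.warn("gene down-selection returned no genes", stacklevel=2)
    return selected
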