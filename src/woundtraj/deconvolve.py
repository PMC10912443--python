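"""Signature-based immune-cell deconvolution of bulk TPM profiles.

Each sample's TPM vector, restricted to the genes shared with a cell-type
signature matrix (also on the TPM scale), is modelled as a non-negative
mixture of the signature columns.  Coefficients are estimated by non-negative
least squares and read directly as cell fractions; the remainder
1 - sum(fractions) is attributed to "other" (unlisted) cell types.  Coefficient
vectors summing above 1 are projected back onto the simplex by normalization.

The sample column is re-normalized to the TPM scale (sum 1e6 over all genes)
inside the model, so externally rescaling a sample's column leaves the
estimated proportions unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import SignatureMatrix


@dataclass
class DeconvolutionResult:
    """Per-sample cell-type proportions, "other" remainder and fit residual."""

    proportions: pd.DataFrame    # samples x cell types
    other_fraction: pd.Series    # per sample
    residual_norm: pd.Series     # per sample, on the fraction scale
    m1_m2_ratio: Optional[pd.Series] = None


def _check_rank(shared: pd.DataFrame) -> None:
    arr = shared.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    tol = s.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < arr.shape[1]:
        null = vt[rank:]
        involved = np.abs(null).max(axis=0) > 1e-8
        cols = [c for c, hit in zip(shared.columns, involved) if hit]
        raise ValueError(
            "signature is rank-deficient on the shared gene set; "
            f"collinear cell types: {cols}")


def estimate_proportions(tpm_matrix: pd.DataFrame,
                         signature: SignatureMatrix) -> DeconvolutionResult:
    """Estimate cell-type fractions per sample from TPM by NNLS.

    Because both the sample vector and signature columns are on the TPM
    scale, an exact noiseless mixture x = sum_c p_c * sig_c is recovered with
    coefficients equal to the p_c themselves.
    """
    shared = tpm_matrix.index.intersection(signature.values.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between TPM matrix and signature")
    sig = signature.values.loc[shared].astype(float)
    _check_rank(sig)
    # Within-model normalization: put every sample back on the sum-1e6 scale.
    col_tot = tpm_matrix.sum(axis=0).to_numpy(dtype=float)
    if (col_tot <= 0).any():
        raise ValueError("sample with non-positive TPM total")
    x = tpm_matrix.loc[shared].to_numpy(dtype=float) * (1e6 / col_tot)
    a = sig.to_numpy()
    # NNLS is solved on the fraction scale so residual norms are comparable.
    scale = 1e6
    props = np.empty((tpm_matrix.shape[1], a.shape[1]))
    resid = np.empty(tpm_matrix.shape[1])
    for j in range(tpm_matrix.shape[1]):
        beta, rnorm = nnls(a / scale, x[:, j] / scale)
        total = beta.sum()
        if total > 1.0:
            beta = beta / total
        props[j] = beta
        resid[j] = rnorm
    samples = tpm_matrix.columns
    proportions = pd.DataFrame(props, index=samples,
                               columns=signature.cell_types)
    other = (1.0 - proportions.sum(axis=1)).clip(lower=0.0)
    other.name = "other"
    return DeconvolutionResult(
        proportions=proportions, other_fraction=other,
        residual_norm=pd.Series(resid, index=samples, name="residual_norm"))


def _find_label(columns, key: str) -> str:
    hits = [c for c in columns if key.lower() in str(c).lower()]
    if len(hits) != 1:
        raise ValueError(
            f"could not identify a unique {key!r} macrophage column among "
            f"{list(columns)}")
    return hits[0]


def m1_m2_ratio(result: DeconvolutionResult,
                m1_label: Optional[str] = None,
                m2_label: Optional[str] = None,
                m2_floor: float = 1e-6) -> pd.Series:
    """Per-sample M1/M2 macrophage proportion ratio.

    A rising ratio marks a persisting pro-inflammatory state; a falling one,
    resolution.  The ratio is recorded missing (NaN, with a warning) when the
    M2 proportion is below ``m2_floor`` rather than returning infinity.
    """
    cols = result.proportions.columns
    m1 = m1_label or _find_label(cols, "M1")
    m2 = m2_label or _find_label(cols, "M2")
    p1 = result.proportions[m1].astype(float)
    p2 = result.proportions[m2].astype(float)
    ratio = p1 / p2.where(p2 >= m2_floor)
    n_missing = int(ratio.isna().sum())
    if n_missing:
        warnings.warn(
            f"M1/M2 ratio undefined for {n_missing} sample(s) with M2 "
            f"proportion below {m2_floor}", stacklevel=2)
    ratio.name = "m1_m2_ratio"
    result.m1_m2_ratio = ratio
    return ratio
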