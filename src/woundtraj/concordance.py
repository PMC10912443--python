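"""Cross-platform concordance between RNA-seq TPM and qRT-PCR threshold cycles.

Matched genes and samples from the two platforms are compared per gene by
Spearman's rank correlation after median-centering both matrices across genes
then across samples.  TPM is log2(TPM + 1)-transformed before centering so
both platforms sit on a log scale; threshold cycles (Ct) are inversely
monotone in abundance, so by default the Ct matrix is negated first, making a
concordant gene show positive rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import median_center


@dataclass
class ConcordanceReport:
    per_gene: pd.DataFrame   # columns: rho, n_samples
    mean_rho: float
    n_genes: int
    rho_threshold: float
    n_above_threshold: int
    fraction_above_threshold: float
    n_undefined: int


def match_platforms(tpm_matrix: pd.DataFrame, pcr: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to shared genes and samples, identically ordered."""
    genes = tpm_matrix.index.intersection(pcr.index)
    samples = tpm_matrix.columns.intersection(pcr.columns)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError(
            f"platforms share {len(genes)} genes and {len(samples)} samples; "
            "nothing to compare")
    dropped_g = (tpm_matrix.shape[0] - len(genes), pcr.shape[0] - len(genes))
    dropped_s = (tpm_matrix.shape[1] - len(samples), pcr.shape[1] - len(samples))
    if any(dropped_g) or any(dropped_s):
        warnings.warn(
            f"platform matching dropped {dropped_g} unmatched genes and "
            f"{dropped_s} unmatched samples (RNA-seq, qRT-PCR)", stacklevel=2)
    return tpm_matrix.loc[genes, samples], pcr.loc[genes, samples]


def per_gene_concordance(tpm_matrix: pd.DataFrame, pcr: pd.DataFrame,
                         ct_orientation: str = "negate",
                         rho_threshold: float = 0.5) -> ConcordanceReport:
    """Per-gene Spearman rho between centered log2 TPM and centered Ct.

    Both inputs must already be matched (same genes and samples; see
    :func:`match_platforms`).  ``ct_orientation="negate"`` (default) flips the
    Ct axis so higher expression scores higher on both platforms; ``"raw"``
    leaves Ct as-is, exactly flipping every rho's sign.
    """
    if ct_orientation not in ("negate", "raw"):
        raise ValueError(f"unknown ct_orientation {ct_orientation!r}")
    if not (tpm_matrix.index.equals(pcr.index)
            and tpm_matrix.columns.equals(pcr.columns)):
        raise ValueError("inputs are not matched; call match_platforms first")
    if tpm_matrix.shape[1] < 3:
        raise ValueError("need at least 3 matched samples")
    expr = median_center(np.log2(tpm_matrix.astype(float) + 1.0),
                         axes=("genes", "samples"))
    ct = pcr.astype(float)
    if ct_orientation == "negate":
        ct = -ct
    ct = median_center(ct, axes=("genes", "samples"))
    # Flag genes flat on either platform before centering: the cross-sample
    # centering step would lend them spurious variation.
    raw_flat = ((tpm_matrix.nunique(axis=1) < 2)
                | (pcr.nunique(axis=1) < 2))
    rhos = {}
    undefined = []
    for gene in expr.index:
        a = expr.loc[gene].to_numpy()
        b = ct.loc[gene].to_numpy()
        if raw_flat[gene] or np.ptp(a) == 0 or np.ptp(b) == 0:
            undefined.append(gene)
            rhos[gene] = np.nan
            continue
        rhos[gene] = float(stats.spearmanr(a, b).statistic)
    if undefined:
        warnings.warn(
            f"{len(undefined)} gene(s) constant on a platform; rho undefined "
            f"and excluded from the mean: {undefined[:5]}", stacklevel=2)
    per_gene = pd.DataFrame({"rho": pd.Series(rhos)})
    per_gene["n_samples"] = tpm_matrix.shape[1]
    defined = per_gene["rho"].dropna()
    n_above = int((defined > rho_threshold).sum())
    return ConcordanceReport(
        per_gene=per_gene,
        mean_rho=float(defined.mean()) if len(defined) else float("nan"),
        n_genes=len(defined),
        rho_threshold=rho_threshold,
        n_above_threshold=n_above,
        fraction_above_threshold=n_above / len(defined) if len(defined) else
        float("nan"),
        n_undefined=len(undefined))
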