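"""Synthetic longitudinal wound cohort with known ground truth.

The study cohort (64 bulk transcriptomes from 21 combat wounds in 18
patients, sampled at serial debridements roughly every 2-3 days between ~3
and ~25 days post-injury, stratified into four colonization-status x outcome
groups) is not public, so this module generates a statistically analogous
cohort with exported ground truth, making every downstream stage testable:

* counts are negative-binomial with mean = sequencing depth x wound effect x
  expected TPM composition, where the expected TPM of each sample is a
  mixture of cell-type expression profiles (10 immune types + "other")
  weighted by designed, linearly drifting proportions;
* genes belonging to designated functional categories additionally carry a
  group-specific exponential (log-linear) time trend whose sign is the
  ground-truth trend class;
* a paired qRT-PCR table maps TPM to threshold cycles through a noisy
  log-linear amplification model, for concordance testing.

All randomness flows from a single integer seed; outputs are bit-identical
across runs with the same design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (WOUND_GROUPS, CountsMatrix, GeneSetCatalog, SignatureMatrix,
                 validate_sample_meta, write_counts, write_gene_sets,
                 write_sample_meta, write_signature)

# The 19 functional categories of wound-relevant biology.
CATEGORIES = (
    "actin", "adhesion", "calcium", "collagen", "cytokine",
    "extracellular matrix", "immune system", "inflammation", "leukocytes",
    "lymphocytes", "metal ion transport", "muscle", "myosin", "neutrophils",
    "oxygen transport", "peptidases", "redox", "T cells", "translation",
)

# The 10 immune cell types whose proportions are deconvolved; "other"
# (stromal, epithelial, muscle...) is the simplex remainder.
CELL_TYPES = (
    "B cells", "CD4 T cells", "CD8 T cells", "Dendritic cells",
    "Macrophages M1", "Macrophages M2", "Monocytes", "Neutrophils",
    "NK cells", "Tregs",
)

_ECM_LIKE = ("extracellular matrix", "collagen", "adhesion", "muscle",
             "actin", "myosin")
_IMMUNE_LIKE = ("immune system", "inflammation", "cytokine", "leukocytes",
                "lymphocytes", "neutrophils", "T cells")


def default_trend_slopes(magnitude: float = 0.1) -> dict[tuple[str, str], float]:
    """Designed log-scale slope (per day) for each (category, group).

    Signs follow the healing biology the cohort emulates: healed wounds shift
    from immune/inflammatory programs to matrix-building programs over time,
    failed wounds show the inverse, with colonization sharpening both.  One
    category per group is left flat: at ~16 samples per group the Spearman
    null distribution (sd ~ 1/sqrt(15) ~ 0.26) makes a truly flat trajectory
    land in |rho| < 0.1 only ~30% of the time, so sign recovery — not flat
    recovery — is what the design benchmarks.
    """
    s = magnitude
    slopes: dict[tuple[str, str], float] = {}

    def fill(group, up, down, flat):
        for c in CATEGORIES:
            if c in flat:
                slopes[(c, group)] = 0.0
            elif c in up:
                slopes[(c, group)] = +s
            elif c in down:
                slopes[(c, group)] = -s
            else:
                raise AssertionError(c)

    fill("colonized/healed",
         up=_ECM_LIKE + ("calcium", "metal ion transport", "redox"),
         down=_IMMUNE_LIKE + ("oxygen transport", "peptidases"),
         flat=("translation",))
    fill("non-colonized/healed",
         up=_ECM_LIKE + ("metal ion transport", "redox", "translation"),
         down=_IMMUNE_LIKE + ("oxygen transport", "peptidases"),
         flat=("calcium",))
    fill("colonized/failed",
         up=_IMMUNE_LIKE + ("metal ion transport", "oxygen transport",
                            "peptidases"),
         down=_ECM_LIKE + ("redox", "translation"),
         flat=("calcium",))
    fill("non-colonized/failed",
         up=_IMMUNE_LIKE + ("metal ion transport", "oxygen transport",
                            "peptidases"),
         down=tuple(c for c in _ECM_LIKE if c != "muscle")
         + ("calcium", "redox", "translation"),
         flat=("muscle",))
    return slopes


def default_mixture_design() -> dict[str, dict[str, tuple[float, float]]]:
    """(start, end) immune proportions per group over the sampled day span.

    Endpoints within each group sum to the same immune total (0.35), so the
    "other" fraction stays constant over time and functional-category
    baselines (expressed mostly by "other") are not confounded by immune
    drift.  Healed colonized wounds resolve (neutrophils and M1 fall, M2, B
    and NK rise); failed colonized wounds inflame (the inverse).
    """
    acute = {"Neutrophils": .10, "Macrophages M1": .06, "Macrophages M2": .02,
             "Monocytes": .04, "NK cells": .02, "B cells": .02,
             "CD4 T cells": .04, "CD8 T cells": .03, "Tregs": .01,
             "Dendritic cells": .01}
    ends = {
        "colonized/healed": {
            "Neutrophils": .03, "Macrophages M1": .02, "Macrophages M2": .06,
            "Monocytes": .03, "NK cells": .05, "B cells": .06,
            "CD4 T cells": .05, "CD8 T cells": .03, "Tregs": .01,
            "Dendritic cells": .01},
        "non-colonized/healed": {
            "Neutrophils": .05, "Macrophages M1": .03, "Macrophages M2": .05,
            "Monocytes": .03, "NK cells": .04, "B cells": .04,
            "CD4 T cells": .05, "CD8 T cells": .04, "Tregs": .01,
            "Dendritic cells": .01},
        "colonized/failed": {
            "Neutrophils": .16, "Macrophages M1": .09, "Macrophages M2": .01,
            "Monocytes": .04, "NK cells": .01, "B cells": .01,
            "CD4 T cells": .01, "CD8 T cells": .01, "Tregs": .005,
            "Dendritic cells": .005},
        "non-colonized/failed": {
            "Neutrophils": .12, "Macrophages M1": .07, "Macrophages M2": .03,
            "Monocytes": .04, "NK cells": .02, "B cells": .015,
            "CD4 T cells": .02, "CD8 T cells": .02, "Tregs": .0075,
            "Dendritic cells": .0075},
    }
    return {g: {ct: (acute[ct], ends[g][ct]) for ct in CELL_TYPES}
            for g in WOUND_GROUPS}


@dataclass
class CohortDesign:
    """Everything that determines a synthetic cohort, besides the seed."""

    n_patients: int = 18
    n_wounds: int = 21
    n_samples: int = 64
    samples_per_wound: tuple[int, int] = (2, 5)
    day_range: tuple[int, int] = (3, 25)
    n_genes: int = 1500
    n_category_genes: int = 20
    n_marker_genes: int = 50
    nb_dispersion: float = 0.05
    wound_effect_sd: float = 0.1
    depth_mean: float = 3e6
    depth_log_sd: float = 0.2
    trend_slopes: dict[tuple[str, str], float] = field(
        default_factory=default_trend_slopes)
    mixture_design: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_mixture_design)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_wounds, self.n_samples,
               self.n_genes, self.n_category_genes) <= 0:
            raise ValueError("counts must be strictly positive")
        if self.day_range[0] < 3:
            raise ValueError("day_range lower bound must be >= 3 (earliest "
                             "sampling bin starts at day 3)")
        if self.day_range[1] < self.day_range[0]:
            raise ValueError("empty day range")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_wounds < self.n_patients // 2 or self.n_wounds < 4:
            raise ValueError("too few wounds for the patient count")
        needed = (len(CATEGORIES) * self.n_category_genes
                  + len(CELL_TYPES) * self.n_marker_genes)
        if needed > self.n_genes:
            raise ValueError(
                f"design infeasible: {needed} category+marker genes exceed "
                f"n_genes={self.n_genes}")
        lo, hi = self.samples_per_wound
        if not (1 <= lo <= hi):
            raise ValueError("invalid samples_per_wound range")
        if not lo * self.n_wounds <= self.n_samples <= hi * self.n_wounds:
            raise ValueError(
                f"n_samples={self.n_samples} unreachable with {self.n_wounds} "
                f"wounds at {lo}-{hi} samples each")


@dataclass
class GroundTruth:
    """Everything needed to score downstream recovery."""

    category_trend_sign: dict[tuple[str, str], str]  # (category, group) -> +/0/-
    true_proportions: pd.DataFrame                   # samples x (cell types + other)
    true_size_factors: pd.Series                     # per sample (depth x wound effect)
    trend_slopes: dict[tuple[str, str], float]


@dataclass
class CohortBundle:
    counts: CountsMatrix
    meta: pd.DataFrame
    catalog: GeneSetCatalog
    signature: SignatureMatrix
    truth: GroundTruth


def _sign(x: float) -> str:
    return "+" if x > 0 else ("-" if x < 0 else "0")


def _allocate_samples(design: CohortDesign, rng: np.random.Generator
                      ) -> list[int]:
    """Per-wound sample counts within range, summing to n_samples."""
    lo, hi = design.samples_per_wound
    counts = np.full(design.n_wounds, lo)
    deficit = design.n_samples - counts.sum()
    while deficit > 0:
        room = np.nonzero(counts < hi)[0]
        pick = rng.choice(room)
        counts[pick] += 1
        deficit -= 1
    return counts.tolist()


def _build_metadata(design: CohortDesign, rng: np.random.Generator
                    ) -> pd.DataFrame:
    # Patients: all wounds of one patient share an outcome.  Wound counts per
    # patient: distribute n_wounds over n_patients (some patients have 2+).
    wounds_per_patient = np.ones(design.n_patients, dtype=int)
    extra = design.n_wounds - design.n_patients
    if extra < 0:
        wounds_per_patient = wounds_per_patient[:design.n_wounds]
    else:
        for i in rng.choice(design.n_patients, size=extra, replace=True):
            wounds_per_patient[i] += 1
    # Round-robin group assignment over wounds keeps the 4 groups balanced;
    # outcome must agree across one patient's wounds, so groups are assigned
    # patient-first with outcome alternating by patient.
    patient_outcome = [
        "healed" if i % 2 == 0 else "failed"
        for i in range(len(wounds_per_patient))]
    rows = []
    wound_idx = 0
    col_counter = {"healed": 0, "failed": 0}
    for p, (n_w, outcome) in enumerate(zip(wounds_per_patient,
                                           patient_outcome)):
        for _ in range(n_w):
            colonization = ("colonized" if col_counter[outcome] % 2 == 0
                            else "non-colonized")
            col_counter[outcome] += 1
            rows.append({"wound_id": f"W{wound_idx:02d}",
                         "patient_id": f"P{p:02d}",
                         "outcome": outcome, "colonization": colonization})
            wound_idx += 1
    wounds = pd.DataFrame(rows)
    per_wound = _allocate_samples(design, rng)
    lo_day, hi_day = design.day_range
    meta_rows = []
    sample_idx = 0
    for (_, w), n_s in zip(wounds.iterrows(), per_wound):
        # Serial debridements every 2-3 days from a start near injury.
        start = int(rng.integers(lo_day, lo_day + 3))
        day = start
        days = []
        for _ in range(n_s):
            days.append(min(day, hi_day))
            day += int(rng.integers(2, 4))
        for d in days:
            meta_rows.append({
                "sample_id": f"S{sample_idx:03d}", "wound_id": w["wound_id"],
                "patient_id": w["patient_id"], "days_post_injury": int(d),
                "outcome": w["outcome"], "colonization": w["colonization"],
                "cfu_per_gram": (float(np.round(rng.lognormal(9, 1), 1))
                                 if w["colonization"] == "colonized" else 0.0),
            })
            sample_idx += 1
    return validate_sample_meta(pd.DataFrame(meta_rows))


def _build_profiles(design: CohortDesign, rng: np.random.Generator
                    ) -> tuple[list[str], pd.DataFrame, GeneSetCatalog,
                               SignatureMatrix, pd.Series]:
    """Gene universe, per-cell-type TPM profiles, category catalog, signature."""
    n_cat = len(CATEGORIES) * design.n_category_genes
    n_mark = len(CELL_TYPES) * design.n_marker_genes
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    cat_genes = genes[:n_cat]
    marker_genes = genes[n_cat:n_cat + n_mark]
    catalog = GeneSetCatalog(sets={
        cat: frozenset(cat_genes[i * design.n_category_genes:
                                 (i + 1) * design.n_category_genes])
        for i, cat in enumerate(CATEGORIES)})
    profiles = pd.DataFrame(0.0, index=genes,
                            columns=list(CELL_TYPES) + ["other"])
    # Background + category genes: expressed by "other" tissue (lognormal,
    # heavy-tailed so some genes clear the TPM>=1000 down-selection), with a
    # small floor in immune types.
    non_marker = [g for g in genes if g not in set(marker_genes)]
    profiles.loc[non_marker, "other"] = rng.lognormal(5.0, 1.5,
                                                      len(non_marker))
    profiles.loc[non_marker, list(CELL_TYPES)] = \
        rng.lognormal(1.0, 0.5, (len(non_marker), len(CELL_TYPES)))
    # Marker genes: high in their own type, near-zero elsewhere.
    for j, ct in enumerate(CELL_TYPES):
        block = marker_genes[j * design.n_marker_genes:
                             (j + 1) * design.n_marker_genes]
        profiles.loc[block, ct] = rng.lognormal(7.0, 0.6, len(block))
        others = [c for c in profiles.columns if c != ct]
        profiles.loc[block, others] += rng.lognormal(
            0.0, 0.3, (len(block), len(others)))
    # Each column is a proper TPM profile: sums to 1e6.
    profiles = profiles * (1e6 / profiles.sum(axis=0))
    signature = SignatureMatrix(
        values=profiles.loc[marker_genes, list(CELL_TYPES)].copy())
    lengths = pd.Series(rng.integers(500, 5001, design.n_genes).astype(float),
                        index=genes, name="length_bp")
    return genes, profiles, catalog, signature, lengths


def _true_proportions(design: CohortDesign, meta: pd.DataFrame) -> pd.DataFrame:
    lo, hi = design.day_range
    span = max(hi - lo, 1)
    rows = {}
    for sid, row in meta.iterrows():
        frac = (row["days_post_injury"] - lo) / span
        frac = min(max(frac, 0.0), 1.0)
        traj = design.mixture_design[row["group"]]
        p = {ct: (1 - frac) * traj[ct][0] + frac * traj[ct][1]
             for ct in CELL_TYPES}
        p["other"] = 1.0 - sum(p.values())
        rows[sid] = p
    props = pd.DataFrame(rows).T.loc[meta.index,
                                     list(CELL_TYPES) + ["other"]]
    if (props.to_numpy() < -1e-12).any():
        raise ValueError("mixture design produced negative proportions")
    return props.clip(lower=0.0)


def nb_counts(mean: np.ndarray, dispersion: float,
              rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2.

    Implemented as a gamma-Poisson mixture; dispersion -> 0 degenerates to
    Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(design: CohortDesign) -> CohortBundle:
    """Generate counts, metadata, gene sets, signature and ground truth."""
    rng = np.random.default_rng(design.seed)
    meta = _build_metadata(design, rng)
    genes, profiles, catalog, signature, lengths = _build_profiles(design, rng)
    props = _true_proportions(design, meta)

    day_mid = 0.5 * (design.day_range[0] + design.day_range[1])
    wound_ids = meta["wound_id"].unique()
    wound_effect = dict(zip(
        wound_ids, np.exp(rng.normal(0.0, design.wound_effect_sd,
                                     len(wound_ids)))))
    depth = np.exp(rng.normal(np.log(design.depth_mean), design.depth_log_sd,
                              len(meta)))

    gene_cat = {}
    for cat, members in catalog.items():
        for g in members:
            gene_cat[g] = cat
    cat_of_gene = [gene_cat.get(g) for g in genes]
    # Per-group vector of log-slopes over genes (0 outside trend categories).
    slope_by_group = {
        group: np.array([design.trend_slopes.get((c, group), 0.0)
                         if c is not None else 0.0 for c in cat_of_gene])
        for group in WOUND_GROUPS}
    length_arr = lengths.to_numpy()

    counts = np.empty((design.n_genes, len(meta)), dtype=np.int64)
    sf_true = np.empty(len(meta))
    profile_arr = profiles.to_numpy()
    col_order = list(profiles.columns)
    for j, (sid, row) in enumerate(meta.iterrows()):
        p = props.loc[sid, col_order].to_numpy(dtype=float)
        x = profile_arr @ p  # expected TPM mixture, sums to 1e6
        x = x * np.exp(slope_by_group[row["group"]]
                       * (row["days_post_injury"] - day_mid))
        rate = x * length_arr
        rate = rate / rate.sum()
        scale = depth[j] * wound_effect[row["wound_id"]]
        mu = scale * rate
        counts[:, j] = nb_counts(mu, design.nb_dispersion, rng)
        sf_true[j] = scale

    counts_df = pd.DataFrame(counts, index=genes, columns=list(meta.index))
    truth = GroundTruth(
        category_trend_sign={k: _sign(v)
                             for k, v in design.trend_slopes.items()},
        true_proportions=props,
        true_size_factors=pd.Series(sf_true, index=meta.index,
                                    name="true_size_factor"),
        trend_slopes=dict(design.trend_slopes))
    return CohortBundle(
        counts=CountsMatrix(values=counts_df, gene_lengths=lengths),
        meta=meta, catalog=catalog, signature=signature, truth=truth)


# ---------------------------------------------------------------------------
# Paired qRT-PCR
# ---------------------------------------------------------------------------

def generate_paired_pcr(counts: CountsMatrix, gene_subset: Sequence[str],
                        ct_noise_sd: float, seed: int,
                        intercept: float = 38.0,
                        efficiency_slope: float = 1.0) -> pd.DataFrame:
    """Threshold-cycle table paired with the cohort's expression.

    Ct = intercept - efficiency_slope * log2(TPM + 1) + N(0, ct_noise_sd):
    higher expression amplifies earlier, giving a lower Ct.  With the default
    intercept/slope the values stay in the instrument-typical ~10-40 range.
    """
    if len(gene_subset) == 0:
        raise ValueError("gene_subset must be non-empty")
    missing = set(gene_subset) - set(counts.gene_ids)
    if missing:
        raise ValueError(f"gene_subset not in counts: {sorted(missing)[:5]}")
    from .normalize import tpm as _tpm
    tpm_matrix = _tpm(counts)
    rng = np.random.default_rng(seed)
    sub = tpm_matrix.loc[list(gene_subset)]
    ct = intercept - efficiency_slope * np.log2(sub + 1.0)
    noise = rng.normal(0.0, ct_noise_sd, ct.shape) if ct_noise_sd > 0 else 0.0
    return ct + noise


def random_tpm(n_genes: int, n_samples: int, seed: int,
               log2_sd: float = 1.5) -> pd.DataFrame:
    """Lognormal TPM matrix with per-gene baselines, columns summing to 1e6."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(4.0, 1.0, n_genes)
    vals = base[:, None] * np.exp(
        np.log(2) * rng.normal(0.0, log2_sd, (n_genes, n_samples)))
    vals = vals * (1e6 / vals.sum(axis=0))
    return pd.DataFrame(vals,
                        index=[f"G{i:05d}" for i in range(n_genes)],
                        columns=[f"S{j:03d}" for j in range(n_samples)])


def calibrate_ct_noise(tpm_matrix: pd.DataFrame, target_mean_rho: float,
                       seed: int, n_seeds: int = 5,
                       intercept: float = 38.0,
                       efficiency_slope: float = 1.0,
                       tol: float = 0.01, max_iter: int = 40) -> float:
    """Bisect the Ct noise sd so mean per-gene Spearman rho hits a target.

    Runs the actual pairing model and concordance computation at each
    candidate sd, averaged over ``n_seeds`` replicate noise draws; the mean
    rho is monotone decreasing in the noise level, so bisection converges.
    """
    from .concordance import per_gene_concordance

    if not 0.0 < target_mean_rho < 1.0:
        raise ValueError("target_mean_rho must be in (0, 1)")
    log_tpm = np.log2(tpm_matrix + 1.0)

    def mean_rho(sd: float) -> float:
        vals = []
        for k in range(n_seeds):
            rng = np.random.default_rng([seed, k])
            ct = intercept - efficiency_slope * log_tpm \
                + rng.normal(0.0, sd, tpm_matrix.shape)
            rep = per_gene_concordance(tpm_matrix, ct,
                                       ct_orientation="negate")
            vals.append(rep.mean_rho)
        return float(np.mean(vals))

    lo, hi = 1e-3, 1.0
    while mean_rho(hi) > target_mean_rho:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("could not bracket the target mean rho")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mean_rho(mid)
        if abs(m - target_mean_rho) < tol:
            return mid
        if m > target_mean_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir: str | Path,
                 counts_format: str = "tsv",
                 pcr: Optional[pd.DataFrame] = None) -> dict[str, str]:
    """Write the full cohort; returns a name -> path manifest fragment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    counts_path = outdir / ("counts.tsv" if counts_format == "tsv"
                            else "counts.mtx")
    write_counts(bundle.counts, counts_path, format=counts_format)
    paths["counts"] = str(counts_path)
    write_sample_meta(bundle.meta, outdir / "metadata.csv")
    paths["metadata"] = str(outdir / "metadata.csv")
    write_gene_sets(bundle.catalog, outdir / "gene_sets.gmt")
    paths["gene_sets"] = str(outdir / "gene_sets.gmt")
    write_signature(bundle.signature, outdir / "signature.tsv")
    paths["signature"] = str(outdir / "signature.tsv")
    truth = {
        "category_trend_sign": {f"{c}|{g}": s for (c, g), s in
                                bundle.truth.category_trend_sign.items()},
        "trend_slopes": {f"{c}|{g}": v for (c, g), v in
                         bundle.truth.trend_slopes.items()},
        "true_proportions": bundle.truth.true_proportions.round(10)
        .to_dict(orient="index"),
        "true_size_factors": bundle.truth.true_size_factors.round(10)
        .to_dict(),
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True))
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    if pcr is not None:
        pcr.to_csv(outdir / "pcr_ct.tsv", sep="\t", index_label="gene_id",
                   float_format="%.10g")
        paths["pcr"] = str(outdir / "pcr_ct.tsv")
    return paths
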