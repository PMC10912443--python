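"""End-to-end orchestration of the wound-trajectory stages.

A single YAML config drives every stage; each stage reads its inputs from
files (either user-supplied paths or the outputs of earlier stages in the run
directory), so running the stages individually composes to exactly the
monolithic ``run_all`` — outputs are bit-for-bit identical given the same
seed.  Every run writes a manifest recording the package version, a hash of
the resolved config, and a hash of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import concordance as conc
from . import deconvolve as dec
from . import dyna as dyna_mod
from . import normalize as norm
from . import rho_pca
from . import synthetic
from . import trajectories as traj
from .io import (CountsMatrix, read_counts, read_gene_sets, read_sample_meta,
                 read_signature)

logger = logging.getLogger("woundtraj")

STAGES = ("simulate", "normalize", "dyna", "trajectories", "deconvolve",
          "pca", "concordance")

DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    # ct_noise_sd calibrated so the packaged cohort's mean cross-platform
    # rho lands near 0.5, the regime the concordance stage is meant to probe.
    "simulate": {"n_pcr_genes": 148, "ct_noise_sd": 0.75},
    "downselect": {"min_mean": 1000.0, "require_all_positive": True},
    "dyna": {"stringency": 0.99, "window_scheme": "consecutive_days",
             "min_samples_per_window": 3, "stratify_by": "outcome"},
    "deconvolve": {"m2_floor": 1e-6},
    "pca": {"observations": "groups", "scale": False},
    "concordance": {"ct_orientation": "negate", "rho_threshold": 0.5},
}


class PipelineConfig:
    """Validated pipeline configuration.

    ``simulate=True`` generates the cohort into ``<outdir>/cohort``;
    otherwise the ``inputs`` mapping must point at existing counts, metadata,
    gene-set, signature (and optionally qRT-PCR) files.
    """

    def __init__(self, outdir: str | Path, seed: int, simulate: bool = True,
                 inputs: Optional[dict[str, str]] = None,
                 params: Optional[dict[str, dict]] = None,
                 counts_format: str = "tsv"):
        self.outdir = Path(outdir)
        if seed is None:
            raise ValueError("a seed is mandatory (no silent default entropy)")
        self.seed = int(seed)
        self.simulate = bool(simulate)
        self.inputs = dict(inputs or {})
        self.counts_format = counts_format
        self.params = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
        for stage, overrides in (params or {}).items():
            if stage not in self.params:
                raise ValueError(f"unknown parameter section {stage!r}")
            self.params[stage].update(overrides)
        self.validate()

    def validate(self) -> None:
        dyna_mod.DynaConfig(**self.params["dyna"])  # range checks
        if not self.simulate:
            required = ("counts", "metadata", "gene_sets", "signature")
            for key in required:
                if key not in self.inputs:
                    raise ValueError(
                        f"simulate is off but no {key!r} input path given")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(
                        f"input path does not exist: {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def resolved(self) -> dict:
        # The output directory is deliberately excluded: it identifies where a
        # run lives, not what it computes, and keeping it out makes runs of
        # the same configuration bit-identical regardless of location.
        return {"seed": self.seed,
                "simulate": self.simulate, "inputs": self.inputs,
                "counts_format": self.counts_format, "params": self.params}

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "id") -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def _cohort_paths(config: PipelineConfig) -> dict[str, Path]:
    base = config.outdir / "cohort"
    defaults = {"counts": base / ("counts.tsv" if config.counts_format == "tsv"
                                  else "counts.mtx"),
                "metadata": base / "metadata.csv",
                "gene_sets": base / "gene_sets.gmt",
                "signature": base / "signature.tsv",
                "pcr": base / "pcr_ct.tsv"}
    return {k: Path(config.inputs.get(k, v)) for k, v in defaults.items()}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> list[Path]:
    p = config.params["simulate"]
    design_kwargs = {k: v for k, v in p.items()
                     if k not in ("n_pcr_genes", "ct_noise_sd")}
    design = synthetic.CohortDesign(seed=config.seed, **design_kwargs)
    bundle = synthetic.generate_cohort(design)
    rng = np.random.default_rng([config.seed, 101])
    pcr_genes = list(rng.choice(bundle.counts.gene_ids,
                                size=int(p["n_pcr_genes"]), replace=False))
    pcr = synthetic.generate_paired_pcr(
        bundle.counts, pcr_genes, ct_noise_sd=float(p["ct_noise_sd"]),
        seed=int(np.random.default_rng([config.seed, 102]).integers(2 ** 31)))
    paths = synthetic.write_cohort(bundle, config.outdir / "cohort",
                                   counts_format=config.counts_format, pcr=pcr)
    return [Path(v) for v in paths.values()]


def _load_inputs(config: PipelineConfig):
    paths = _cohort_paths(config)
    counts = read_counts(paths["counts"], format=config.counts_format)
    meta = read_sample_meta(paths["metadata"])
    catalog = read_gene_sets(paths["gene_sets"])
    signature = read_signature(paths["signature"])
    return counts, meta, catalog, signature, paths


def stage_normalize(config: PipelineConfig) -> list[Path]:
    counts, *_ = _load_inputs(config)
    normalized = norm.normalize_counts(counts)
    tpm = norm.tpm(counts)
    out = config.outdir / "normalize"
    _write_tsv(normalized.size_factors.to_frame(), out / "size_factors.tsv",
               "sample_id")
    _write_tsv(normalized.values, out / "normalized_counts.tsv", "gene_id")
    _write_tsv(tpm, out / "tpm.tsv", "gene_id")
    return [out / "size_factors.tsv", out / "normalized_counts.tsv",
            out / "tpm.tsv"]


def stage_dyna(config: PipelineConfig) -> list[Path]:
    _, meta, _, _, _ = _load_inputs(config)
    tpm = pd.read_csv(config.outdir / "normalize" / "tpm.tsv", sep="\t",
                      index_col=0)
    ds = config.params["downselect"]
    genes = norm.downselect_genes(tpm, min_mean=float(ds["min_mean"]),
                                  require_all_positive=ds["require_all_positive"])
    cfg = dyna_mod.DynaConfig(**config.params["dyna"])
    windows = dyna_mod.build_windows(meta, cfg)
    networks = dyna_mod.dyna_networks(tpm.loc[genes], meta, cfg)
    series = dyna_mod.complexity_trajectory(networks, windows)
    out = config.outdir / "dyna"
    out.mkdir(parents=True, exist_ok=True)
    (out / "downselected_genes.txt").write_text("\n".join(genes) + "\n")
    series.to_csv(out / "complexity.tsv", sep="\t", index=False,
                  float_format="%.10g")
    written = [out / "downselected_genes.txt", out / "complexity.tsv"]
    for stratum, nets in networks.items():
        for net in nets:
            if net is None:
                continue
            stem = f"{stratum}_{net.window}".replace("/", "-")
            dyna_mod.to_edge_list(net, out / f"edges_{stem}.tsv")
            dyna_mod.to_graphml(net, out / f"network_{stem}.graphml")
            written += [out / f"edges_{stem}.tsv",
                        out / f"network_{stem}.graphml"]
    return written


def stage_trajectories(config: PipelineConfig) -> list[Path]:
    _, meta, catalog, _, _ = _load_inputs(config)
    normalized = pd.read_csv(
        config.outdir / "normalize" / "normalized_counts.tsv", sep="\t",
        index_col=0)
    summed = traj.sum_category_expression(normalized, catalog)
    table = traj.build_trajectory_table(summed, meta, kind="category")
    tally = traj.classify_trends(table)
    out = config.outdir / "trajectories"
    _write_tsv(summed, out / "category_expression.tsv", "category")
    table.to_csv(out / "category_trajectories.tsv", sep="\t", index=False,
                 float_format="%.10g")
    tally.to_csv(out / "category_trend_tally.tsv", sep="\t", index=False)
    return [out / "category_expression.tsv",
            out / "category_trajectories.tsv",
            out / "category_trend_tally.tsv"]


def stage_deconvolve(config: PipelineConfig) -> list[Path]:
    _, meta, _, signature, _ = _load_inputs(config)
    tpm = pd.read_csv(config.outdir / "normalize" / "tpm.tsv", sep="\t",
                      index_col=0)
    result = dec.estimate_proportions(tpm, signature)
    ratio = dec.m1_m2_ratio(result,
                            m2_floor=float(config.params["deconvolve"]
                                           ["m2_floor"]))
    combined = result.proportions.copy()
    combined["other"] = result.other_fraction
    combined["residual_norm"] = result.residual_norm
    combined["m1_m2_ratio"] = ratio
    cells = traj.build_trajectory_table(result.proportions.T, meta,
                                        kind="cell_type")
    ratio_tab = traj.build_trajectory_table(ratio.to_frame().T, meta,
                                            kind="m1_m2_ratio")
    table = pd.concat([cells, ratio_tab], ignore_index=True)
    tally = traj.classify_trends(table)
    out = config.outdir / "deconvolve"
    _write_tsv(combined, out / "proportions.tsv", "sample_id")
    table.to_csv(out / "cell_trajectories.tsv", sep="\t", index=False,
                 float_format="%.10g")
    tally.to_csv(out / "cell_trend_tally.tsv", sep="\t", index=False)
    return [out / "proportions.tsv", out / "cell_trajectories.tsv",
            out / "cell_trend_tally.tsv"]


def stage_pca(config: PipelineConfig) -> list[Path]:
    cat_tab = pd.read_csv(
        config.outdir / "trajectories" / "category_trajectories.tsv",
        sep="\t")
    cell_tab = pd.read_csv(
        config.outdir / "deconvolve" / "cell_trajectories.tsv", sep="\t")
    table = pd.concat([cat_tab, cell_tab], ignore_index=True)
    matrix = rho_pca.assemble_rho_matrix(table)
    p = config.params["pca"]
    result = rho_pca.pca(matrix, observations=p["observations"],
                         scale=bool(p["scale"]))
    report = rho_pca.group_separation_report(result)
    out = config.outdir / "pca"
    _write_tsv(matrix.values, out / "rho_matrix.tsv", "feature")
    _write_tsv(result.scores, out / "scores.tsv", "observation")
    _write_tsv(result.loadings, out / "loadings.tsv", "variable")
    _write_tsv(result.contributions, out / "contributions.tsv", "variable")
    _write_tsv(result.variance_explained.to_frame(),
               out / "variance_explained.tsv", "component")
    payload = {"separation": report, "excluded_features": matrix.excluded}
    (out / "separation.json").write_text(json.dumps(payload, indent=1,
                                                    sort_keys=True))
    return [out / "rho_matrix.tsv", out / "scores.tsv", out / "loadings.tsv",
            out / "contributions.tsv", out / "variance_explained.tsv",
            out / "separation.json"]


def stage_concordance(config: PipelineConfig) -> list[Path]:
    paths = _cohort_paths(config)
    if not paths["pcr"].exists():
        logger.info("no qRT-PCR table; skipping concordance stage")
        return []
    tpm = pd.read_csv(config.outdir / "normalize" / "tpm.tsv", sep="\t",
                      index_col=0)
    pcr = pd.read_csv(paths["pcr"], sep="\t", index_col=0)
    m_tpm, m_pcr = conc.match_platforms(tpm, pcr)
    p = config.params["concordance"]
    report = conc.per_gene_concordance(m_tpm, m_pcr,
                                       ct_orientation=p["ct_orientation"],
                                       rho_threshold=float(p["rho_threshold"]))
    out = config.outdir / "concordance"
    _write_tsv(report.per_gene, out / "per_gene_rho.tsv", "gene_id")
    summary = {"mean_rho": report.mean_rho, "n_genes": report.n_genes,
               "rho_threshold": report.rho_threshold,
               "n_above_threshold": report.n_above_threshold,
               "fraction_above_threshold": report.fraction_above_threshold,
               "n_undefined": report.n_undefined}
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    return [out / "per_gene_rho.tsv", out / "summary.json"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "dyna": stage_dyna,
    "trajectories": stage_trajectories,
    "deconvolve": stage_deconvolve,
    "pca": stage_pca,
    "concordance": stage_concordance,
}


def run_stage(config: PipelineConfig, stage: str) -> list[Path]:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}")
    logger.info("running stage %s", stage)
    try:
        return _STAGE_FUNCS[stage](config)
    except Exception as exc:
        config.outdir.mkdir(parents=True, exist_ok=True)
        (config.outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_all(config: PipelineConfig, skip_simulate: bool = False
            ) -> dict[str, Any]:
    """Run every stage in order; returns and writes the run manifest."""
    failed_marker = config.outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    outputs: dict[str, list[str]] = {}
    for stage in STAGES:
        if stage == "simulate" and (skip_simulate or not config.simulate):
            continue
        outputs[stage] = [str(p) for p in run_stage(config, stage)]
    manifest = {
        "tool": "woundtraj",
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "stages": {stage: {str(Path(p).relative_to(config.outdir)):
                           _sha256(Path(p)) for p in paths}
                   for stage, paths in outputs.items()},
    }
    (config.outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
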