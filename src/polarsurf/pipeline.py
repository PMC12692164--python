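"""Full-pipeline orchestration with a machine-readable run report.

Stages: contaminant QC -> normalization -> polarization -> topology QC ->
covariance clustering -> report.  Every feature excluded anywhere is
accounted for in the report, so input count = output count + exclusions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import io
from .clusters import CovarianceClusterModel, crosstab
from .normalize import cv_summary
from .polarization import PolarizationModel
from .topology import calls_to_frame, map_biotin_sites, summaries_to_frame, topology_summary

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("polarsurf")


@dataclass
class RunConfig:
    protein_quant: str
    design: str
    outdir: str
    peptide_quant: str | None = None
    peptides: str | None = None  # peptide records TSV (for topology QC)
    topology: str | None = None
    contaminants: str | None = None  # TSV with a protein_id column
    annotations: str | None = None  # protein_id + annotation columns
    alpha: float = 0.05
    bio_threshold: float = 60.0
    r_strong: float = 0.95
    r_intra: float = 0.9
    min_pairs: int = 3
    min_shared: int = 6
    min_cluster: int = 10
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 50 <= self.bio_threshold <= 100:
            raise ValueError("bio_threshold must be in [50, 100]")
        for name in ("r_strong", "r_intra"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # sections (paths:, thresholds:, ...)
                flat.update(val)
            else:
                flat[key] = val
        return cls(**flat)

    def validate_paths(self) -> None:
        for name in ("protein_quant", "design", "peptide_quant", "peptides",
                     "topology", "contaminants", "annotations"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kw):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all result tables plus report.json."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    report: dict = {
        "package": "polarsurf",
        "version": _pkg_version("polarsurf"),
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "bio_threshold_pct": config.bio_threshold,
            "r_strong": config.r_strong,
            "r_intra": config.r_intra,
            "min_pairs": config.min_pairs,
            "min_shared": config.min_shared,
            "min_cluster": config.min_cluster,
        },
        "counts": {},
        "qc": {},
    }
    try:
        design = _read_inputs_stage(config, report)
        matrix, contaminant_ids = _contaminant_stage(config, report)
        results = _polarization_stage(config, report, matrix, design, outdir)
        ok_ids = _topology_stage(config, report, outdir, results)
        _cluster_stage(config, report, results, contaminant_ids, outdir)
    finally:
        with open(outdir / "report.json", "w") as out:
            json.dump(report, out, indent=2, default=str)
        logger.removeHandler(fh)
        fh.close()
    return report


@_stage("read_inputs")
def _read_inputs_stage(config: RunConfig, report: dict) -> io.SampleDesign:
    design = io.read_design(config.design)
    report["counts"]["bioreplicate_pairs"] = design.n_pairs
    report["counts"]["samples"] = len(design.sample_ids)
    return design


@_stage("contaminants")
def _contaminant_stage(config: RunConfig, report: dict):
    matrix = io.read_quant_table(config.protein_quant, dialect="canonical", level="protein")
    report["counts"]["proteins_input"] = len(matrix.feature_ids)
    report["counts"]["zero_cells_converted_to_missing"] = getattr(
        matrix, "n_zero_converted", 0
    )
    contaminant_ids: set[str] = set()
    if config.contaminants:
        cont = pd.read_csv(config.contaminants, sep="\t", dtype=str)
        contaminant_ids = set(cont["protein_id"]) & set(matrix.feature_ids)
    report["counts"]["contaminants_flagged"] = len(contaminant_ids)
    return matrix, contaminant_ids


@_stage("polarization")
def _polarization_stage(config, report, matrix, design, outdir):
    model = PolarizationModel(
        matrix, design, normalization="replicate_average", min_pairs=config.min_pairs
    )
    results = model.fit(alpha=config.alpha, bio_threshold_pct=config.bio_threshold)
    cv = cv_summary(results.normalization.normalized, design)
    cv_raw = cv_summary(matrix, design)
    report["qc"]["median_cv_pct_raw"] = cv_raw.median_cv_pct
    report["qc"]["median_cv_pct_normalized"] = cv.median_cv_pct
    report["counts"]["pairs_dropped_missing_side"] = len(results.normalization.dropped_pairs)
    tested = int(results.table["p_value"].notna().sum())
    report["counts"]["proteins_tested"] = tested
    report["counts"]["proteins_excluded_min_pairs"] = (
        len(results.table) - tested
    )
    report["counts"]["significant_q"] = results.n_significant
    report["counts"]["apical_core"] = len(results.core_apical)
    report["counts"]["basolateral_core"] = len(results.core_basolateral)
    floor = results.randomization_floor(n_perm=config.n_permutations, seed=config.seed)
    report["qc"]["randomization_floor_pct"] = floor.floor_pct
    report["qc"]["randomization_n_permutations"] = floor.n_permutations
    results.table.to_csv(outdir / "polarization.tsv", sep="\t", na_rep=io.MISSING)
    io.write_quant_table(results.normalization.normalized, outdir / "normalized.tsv")
    volcano = results.table[["apical_fraction_pct", "log2_fc", "q_value", "class"]]
    volcano.to_csv(outdir / "volcano.tsv", sep="\t", na_rep=io.MISSING)
    return results


@_stage("topology")
def _topology_stage(config, report, outdir, results):
    if not (config.peptides and config.topology):
        return set()
    records = io.read_peptide_records(config.peptides)
    topo = io.read_topology(config.topology)
    calls = map_biotin_sites(records, topo)
    summaries, rates = topology_summary(calls, topo)
    calls_to_frame(calls).to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
    summaries_to_frame(summaries).to_csv(
        outdir / "topology_summary.tsv", sep="\t", index=False
    )
    report["qc"]["site_extracellular_rate"] = rates.site_extracellular_rate
    report["qc"]["protein_any_extracellular_rate"] = rates.protein_any_rate
    report["qc"]["protein_all_extracellular_rate"] = rates.protein_all_rate
    report["counts"]["biotin_sites"] = rates.n_sites
    report["counts"]["tm_proteins_with_sites"] = rates.n_tm_proteins
    ok_ids = {s.protein_id for s in summaries if s.any_extracellular}
    results.set_biotin_ok(ok_ids)
    results.table.to_csv(outdir / "polarization.tsv", sep="\t", na_rep=io.MISSING)
    return ok_ids


@_stage("clusters")
def _cluster_stage(config, report, results, contaminant_ids, outdir):
    # clustering sees the raw matrix (median-normalized internally): the
    # pair-anchored normalization removes the co-variation the clusters need
    model = CovarianceClusterModel(
        results.model.matrix,
        core_apical=results.core_apical,
        core_basolateral=results.core_basolateral,
        exclude=contaminant_ids,
        r_strong=config.r_strong,
        r_intra_min=config.r_intra,
        min_size=config.min_cluster,
        min_shared=config.min_shared,
    )
    cres = model.fit(alpha=config.alpha)
    cres.membership_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    cres.stats_frame().to_csv(outdir / "cluster_stats.tsv", sep="\t", index=False)
    long = cres.correlation.r.stack().rename("r")
    long.index.names = ["protein_a", "protein_b"]
    long = long.reset_index()
    long = long[long["protein_a"] < long["protein_b"]]
    long[long["r"].abs() > 0.5].to_csv(
        outdir / "correlations.tsv", sep="\t", index=False
    )
    report["counts"]["cluster_background"] = len(cres.correlation.protein_ids)
    report["counts"]["strong_correlation_subset"] = len(cres.strong_subset)
    report["counts"]["clusters_accepted"] = len(cres.clusters.accepted)
    report["counts"]["clusters_apical"] = len(cres.clusters.accepted_by_polarity("apical"))
    report["counts"]["clusters_basolateral"] = len(
        cres.clusters.accepted_by_polarity("basolateral")
    )
    report["counts"]["proteins_in_accepted_clusters"] = sum(
        c.size for c in cres.clusters.accepted
    )
    if config.annotations:
        ann = pd.read_csv(config.annotations, sep="\t", dtype=str)
        mapping = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
        crosstab(cres.clusters.accepted, mapping).to_csv(
            outdir / "crosstab.tsv", sep="\t", index=False
        )
    return cres
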