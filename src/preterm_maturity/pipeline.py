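"""End-to-end orchestration of the analysis stages.

A :class:`RunConfig` (loadable from YAML) carries the input paths, stage
parameters, and seeds.  Every stage writes its artifacts under the output
directory tagged with a hash of the configuration, and the combined report
refuses to mix artifacts from different configurations.  Stage functions
log one structured line each (shapes in/out, seed) via the standard
``logging`` module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, growth, maturity, metabolome, microbiome, timeseries
from .errors import ConfigurationError, DataError

log = logging.getLogger("preterm_maturity")


@dataclass
class RunConfig:
    """Inputs, stage toggles, and all stage parameters for a run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    metabolites_path: str | None = None
    out_dir: str = "results"
    # microbiome preprocessing
    min_count: int = 10
    min_prevalence: float = 0.10
    min_reads: int = 50
    rarefy_depth: int = 5000
    css_quantile: float = 0.5
    # maturity engine
    n_trees: int = 500
    n_perm: int = 1000
    cv_folds: int | None = None
    select_tol: float = 0.05
    n_features: int | None = None
    bins: tuple[float, ...] = maturity.DEFAULT_BINS
    # timeseries / clustering
    time_var: str = "study_week"
    threshold: float = 0.0
    k_range: tuple[int, ...] = tuple(range(1, 9))
    gap_B: int = 50
    # metabolome
    acylcarnitine_only: bool = False
    full_enteral_only: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("counts_path", "metadata_path", "metabolites_path"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{key} does not exist: {value}")
        return cfg

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(config: RunConfig, name: str, payload: dict) -> Path:
    path = _out(config) / name
    payload = dict(payload, config_hash=config.hash())
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def load_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"infant_id", "pma_weeks", "study_week", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata lacks columns {sorted(missing)}")
    return meta


def preprocess_microbiome(
    config: RunConfig, table: microbiome.CountTable
) -> tuple[microbiome.CountTable, dict]:
    """Sparse-OTU filter -> low-depth sample filter -> rarefaction."""
    filtered = microbiome.filter_sparse_otus(
        table, config.min_count, config.min_prevalence
    )
    filtered, depth_report = microbiome.filter_low_depth_samples(
        filtered, config.min_reads
    )
    rarefied, rarefy_report = microbiome.rarefy(
        filtered, config.rarefy_depth, seed=config.seed
    )
    report = {"low_depth": depth_report, "rarefaction": rarefy_report,
              "n_features": rarefied.n_features, "n_samples": rarefied.n_samples}
    log.info(
        "preprocess_microbiome: %d x %d -> %d x %d (seed=%d)",
        table.n_features, table.n_samples,
        rarefied.n_features, rarefied.n_samples, config.seed,
    )
    return rarefied, report


def run_microbiota_maturity(
    config: RunConfig,
    table: microbiome.CountTable | None = None,
    metadata: pd.DataFrame | None = None,
    validation: microbiome.CountTable | None = None,
) -> dict:
    """Filter -> rarefy -> fit the maturity model on appropriate-growth
    samples -> permutation test -> spline -> score every group.

    Returns paths of the written artifacts plus the fitted model and scores.
    """
    if table is None:
        table = microbiome.read_count_table(config.counts_path)
    if metadata is None:
        metadata = load_metadata(config.metadata_path)
    rarefied, prep_report = preprocess_microbiome(config, table)
    meta = metadata.loc[rarefied.sample_ids]
    X = rarefied.counts.T.astype(float)
    ag = meta.index[meta["group"] == "appropriate"]
    model = maturity.train_maturity_model(
        X.loc[ag],
        meta.loc[ag, "pma_weeks"],
        meta.loc[ag, "infant_id"],
        n_trees=config.n_trees,
        cv_folds=config.cv_folds,
        select_tol=config.select_tol,
        n_perm=config.n_perm,
        n_features=config.n_features,
        bins=config.bins,
        seed=config.seed,
    )
    scores = maturity.score_maturity(model, X, meta["pma_weeks"])
    # training samples are re-scored from their out-of-bag predictions so
    # the reference group is not flattered by in-sample fits
    ref_scores = maturity.reference_scores(model)
    scores.loc[ref_scores.index, ref_scores.columns] = ref_scores
    scores["group"] = meta["group"]
    out = _out(config)
    model_path = out / "microbiota_maturity_model.joblib"
    maturity.save_model(model, model_path)
    scores_path = out / "microbiota_maturity_scores.tsv"
    scores.to_csv(scores_path, sep="\t", index_label="sample_id")
    result = {
        "model": model,
        "scores": scores,
        "prep_report": prep_report,
    }
    if validation is not None:
        aligned, map_report = microbiome.closed_reference_map(rarefied, validation)
        result["validation_map_report"] = map_report
    summary = {
        "stage": "microbiota_maturity",
        "r_squared": model.r_squared,
        "n_selected_features": len(model.feature_ids),
        "selected_features": model.feature_ids,
        "permutation_p": None if model.permutation is None else model.permutation.p_value,
        "seed": config.seed,
        "prep": prep_report,
    }
    result["summary_path"] = str(
        _write_json(config, "microbiota_maturity_summary.json", summary)
    )
    log.info(
        "microbiota_maturity: R2=%.3f, %d features, p=%s",
        model.r_squared, len(model.feature_ids),
        summary["permutation_p"],
    )
    return result


def run_metabolome_maturity(
    config: RunConfig,
    table: metabolome.MetaboliteTable | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Targeted-chain preprocessing, then the identical maturity engine on
    the metabolite matrix, restricted (by default) to samples collected on
    complete enteral nutrition."""
    if table is None:
        values = pd.read_csv(config.metabolites_path, index_col=0)
        table = metabolome.MetaboliteTable(values)
    if metadata is None:
        metadata = load_metadata(config.metadata_path)
    prepped, prep_report = metabolome.prepare_targeted(table)
    meta = metadata.loc[prepped.sample_ids]
    keep = (
        meta.index[meta.get("full_enteral", pd.Series(True, index=meta.index)).astype(bool)]
        if config.full_enteral_only
        else meta.index
    )
    # the maturity model uses complete cases only (the targeted chain does
    # not impute); samples missing any retained metabolite are dropped
    complete = prepped.values[keep].notna().all(axis=0)
    keep = keep[complete]
    X = prepped.values[keep].T
    meta = meta.loc[keep]
    ag = meta.index[meta["group"] == "appropriate"]
    model = maturity.train_maturity_model(
        X.loc[ag],
        meta.loc[ag, "pma_weeks"],
        meta.loc[ag, "infant_id"],
        n_trees=config.n_trees,
        cv_folds=config.cv_folds,
        select_tol=config.select_tol,
        n_perm=config.n_perm,
        n_features=config.n_features,
        bins=config.bins,
        seed=config.seed,
    )
    scores = maturity.score_maturity(model, X, meta["pma_weeks"])
    ref_scores = maturity.reference_scores(model)
    scores.loc[ref_scores.index, ref_scores.columns] = ref_scores
    scores["group"] = meta["group"]
    out = _out(config)
    maturity.save_model(model, out / "metabolome_maturity_model.joblib")
    scores.to_csv(out / "metabolome_maturity_scores.tsv", sep="\t",
                  index_label="sample_id")
    summary = {
        "stage": "metabolome_maturity",
        "modality": "acylcarnitine-only" if config.acylcarnitine_only else "combined",
        "r_squared": model.r_squared,
        "n_selected_features": len(model.feature_ids),
        "selected_features": model.feature_ids,
        "permutation_p": None if model.permutation is None else model.permutation.p_value,
        "seed": config.seed,
        "prep": prep_report,
    }
    summary_path = _write_json(config, "metabolome_maturity_summary.json", summary)
    log.info(
        "metabolome_maturity: R2=%.3f, %d features", model.r_squared,
        len(model.feature_ids),
    )
    return {"model": model, "scores": scores, "summary_path": str(summary_path),
            "prep_report": prep_report}


def run_clustering(config: RunConfig, table=None, metadata=None) -> dict:
    """JSD -> PCoA -> gap-statistic k -> PAM -> time/group association."""
    if table is None:
        table = microbiome.read_count_table(config.counts_path)
    if metadata is None:
        metadata = load_metadata(config.metadata_path)
    rarefied, _ = preprocess_microbiome(config, table)
    rel = rarefied.relative_abundance()
    dm = community.jsd_matrix(rel)
    ord_ = community.pcoa(dm)
    k, gap_curve = community.gap_statistic(
        ord_.coordinates, k_range=config.k_range, B=config.gap_B, seed=config.seed
    )
    solution = community.pam_cluster(ord_.coordinates, max(k, 2))
    solution.gap_curve = gap_curve
    assoc = community.cluster_group_time_association(
        solution.assignments, metadata.loc[solution.assignments.index],
        time_var=config.time_var, seed=config.seed,
    )
    out = _out(config)
    solution.assignments.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                           index_label="sample_id")
    gap_curve.to_csv(out / "gap_curve.tsv", sep="\t", index=False)
    summary = {"stage": "clustering", "chosen_k": int(k),
               "cluster_sizes": solution.assignments.value_counts().to_dict()}
    _write_json(config, "clustering_summary.json", summary)
    log.info("clustering: chose k=%d", k)
    return {"k": k, "solution": solution, "association": assoc,
            "ordination": ord_}


def run_timeseries(config: RunConfig, table=None, metadata=None,
                   rank: str = "family") -> pd.DataFrame:
    """CSS + log2 normalization, taxonomy aggregation, then the
    interval-detection permutation test per taxon."""
    if table is None:
        table = microbiome.read_count_table(config.counts_path)
    if metadata is None:
        metadata = load_metadata(config.metadata_path)
    filtered = microbiome.filter_sparse_otus(table, config.min_count,
                                             config.min_prevalence)
    filtered, _ = microbiome.filter_low_depth_samples(filtered, config.min_reads)
    agg = microbiome.aggregate_taxonomy(filtered, rank=rank)
    normalized, _ = microbiome.css_normalize(agg, config.css_quantile)
    values = np.log2(normalized + 1.0)
    intervals = timeseries.differential_intervals(
        values, metadata, time_var=config.time_var, n_perm=config.n_perm,
        threshold=config.threshold, seed=config.seed,
    )
    intervals.to_csv(_out(config) / "intervals.tsv", sep="\t", index=False)
    return intervals


_REPORT_SECTIONS = {
    "microbiota_maturity": "microbiota_maturity_summary.json",
    "metabolome_maturity": "metabolome_maturity_summary.json",
    "clustering": "clustering_summary.json",
}


def run_full_report(config: RunConfig, stages=None) -> Path:
    """Assemble a markdown report from the stage summary JSONs.

    ``stages`` limits which sections are required; a stage not requested is
    marked skipped.  Artifacts carrying a different config hash are refused.
    """
    out = _out(config)
    stages = list(stages) if stages is not None else list(_REPORT_SECTIONS)
    lines = ["# Maturity analysis report", "",
             f"Configuration hash: `{config.hash()}`", ""]
    for stage, fname in _REPORT_SECTIONS.items():
        lines.append(f"## {stage}")
        path = out / fname
        if stage not in stages:
            lines.append("_skipped_\n")
            continue
        if not path.exists():
            raise DataError(f"missing artifact for stage {stage!r}: {path}")
        payload = json.loads(path.read_text())
        if payload.get("config_hash") != config.hash():
            raise DataError(
                f"artifact {path} was produced under a different configuration"
            )
        for key, value in payload.items():
            if key in ("config_hash", "stage", "prep"):
                continue
            lines.append(f"- {key}: {value}")
        lines.append("")
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
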