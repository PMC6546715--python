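"""Serum-metabolite QC and transformation chains.

Covers targeted panels (flow-injection and LC-MS/MS acylcarnitines, amino
acids) and non-targeted GC-MS intensities.  Values live in a metabolite-by-
sample DataFrame where NaN marks *missing* (not measured / below volume) as
distinct from a measured zero (below limit of detection).

Two canonical chains are exposed:

* targeted:  detection filters -> half-minimum zero replacement -> log2 ->
  Pareto scaling (no batch structure).
* GC-MS:     detection filters -> log2 -> per-batch mean-centering -> KNN
  imputation -> Pareto scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import ConfigurationError, DataError


@dataclass
class MetaboliteTable:
    """A metabolite-by-sample numeric matrix with panel/batch annotations.

    ``values`` holds concentrations or intensities (NaN = missing);
    ``detected_mask`` flags entries measured above the limit of detection;
    ``batch`` maps sample id -> batch label (required for GC-MS panels).
    """

    values: pd.DataFrame
    panel: str = "targeted_AC_AA"
    batch: pd.Series | None = None
    detected_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate metabolite ids")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample ids")
        if self.detected_mask is None:
            # default: detected = measured and strictly positive
            self.detected_mask = self.values.notna() & (self.values > 0)
        else:
            self.detected_mask = self.detected_mask.reindex(
                index=self.values.index, columns=self.values.columns
            ).fillna(False).astype(bool)
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()][0]
                raise DataError(f"sample {missing!r} has no batch label")
        elif self.panel == "gcms":
            raise DataError("gcms panel requires batch labels")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def _with(self, values: pd.DataFrame, mask: pd.DataFrame | None = None):
        batch = None if self.batch is None else self.batch.loc[values.columns]
        if mask is None:
            mask = self.detected_mask.loc[values.index, values.columns]
        return MetaboliteTable(values, self.panel, batch, mask)


@dataclass(frozen=True)
class PrepConfig:
    """Knobs for the preprocessing chains."""

    max_undetected_frac: float = 0.25
    min_sample_detect_frac: float = 0.50
    knn_k: int = 10
    log_base: float = 2.0
    scaling: str = "pareto"

    def __post_init__(self) -> None:
        for name in ("max_undetected_frac", "min_sample_detect_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.knn_k < 1:
            raise ConfigurationError(f"knn_k must be >= 1, got {self.knn_k}")


def drop_undetected_metabolites(
    table: MetaboliteTable, max_undetected_frac: float = 0.25
) -> tuple[MetaboliteTable, dict]:
    """Remove metabolites undetected in strictly more than
    ``max_undetected_frac`` of samples (boundary kept at exactly the
    threshold)."""
    frac = 1.0 - table.detected_mask.mean(axis=1)
    drop = frac.index[frac > max_undetected_frac]
    keep = frac.index[frac <= max_undetected_frac]
    report = {
        "dropped_metabolites": {m: float(frac[m]) for m in drop},
        "threshold": max_undetected_frac,
    }
    return table._with(table.values.loc[keep].copy()), report


def drop_sparse_samples(
    table: MetaboliteTable, min_sample_detect_frac: float = 0.50
) -> tuple[MetaboliteTable, dict]:
    """Remove samples in which strictly fewer than
    ``min_sample_detect_frac`` of metabolites were detected."""
    frac = table.detected_mask.mean(axis=0)
    keep = [s for s in table.sample_ids if frac[s] >= min_sample_detect_frac]
    drop = [s for s in table.sample_ids if frac[s] < min_sample_detect_frac]
    if not keep:
        raise DataError("sample detection filter removed every sample")
    report = {"dropped_samples": drop, "threshold": min_sample_detect_frac}
    return table._with(table.values[keep].copy()), report


def replace_zeros_half_min(table: MetaboliteTable) -> MetaboliteTable:
    """Replace measured zeros by half the minimum positive value per
    metabolite; missing entries are untouched."""
    values = table.values.copy()
    for m in values.index:
        row = values.loc[m]
        if (row.fillna(0) < 0).any():
            raise DataError(f"negative value in metabolite {m!r}")
        positive = row[row > 0]
        zeros = row == 0
        if zeros.any():
            if positive.empty:
                raise DataError(
                    f"metabolite {m!r} has no positive value; cannot "
                    "half-minimum-replace its zeros"
                )
            values.loc[m, zeros] = positive.min() / 2.0
    return table._with(values)


def log_transform(table: MetaboliteTable, base: float = 2.0) -> MetaboliteTable:
    """Elementwise log of non-missing values; raises if any value <= 0
    (zeros must be replaced first)."""
    arr = table.values.to_numpy(float)
    bad = np.argwhere((arr <= 0) & ~np.isnan(arr))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-positive value at metabolite {table.values.index[i]!r}, "
            f"sample {table.values.columns[j]!r}; replace zeros before log"
        )
    values = pd.DataFrame(
        np.log(arr) / np.log(base),
        index=table.values.index,
        columns=table.values.columns,
    )
    return table._with(values)


def pareto_scale(table: MetaboliteTable) -> MetaboliteTable:
    """Per metabolite: subtract the mean, divide by sqrt(sample SD)."""
    values = table.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    if (values.notna().sum(axis=1) < 2).any():
        m = values.index[values.notna().sum(axis=1) < 2][0]
        raise DataError(f"metabolite {m!r} has <2 observed samples")
    if (sds == 0).any():
        m = sds.index[sds == 0][0]
        raise DataError(f"metabolite {m!r} has zero variance; cannot Pareto scale")
    scaled = values.sub(means, axis=0).div(np.sqrt(sds), axis=0)
    return table._with(scaled)


def batch_mean_center(table: MetaboliteTable) -> MetaboliteTable:
    """Subtract, per metabolite and batch, the batch mean of observed values."""
    if table.batch is None:
        raise DataError("batch labels required for batch mean-centering")
    values = table.values.copy()
    for b in pd.unique(table.batch):
        cols = table.batch.index[table.batch == b]
        block = values[cols]
        means = block.mean(axis=1)
        if means.isna().any():
            warnings.warn(
                f"batch {b!r} has metabolites with no observed values; "
                "those entries stay missing",
                stacklevel=2,
            )
            means = means.fillna(0.0)
        values[cols] = block.sub(means, axis=0)
    return table._with(values)


def knn_impute(table: MetaboliteTable, k: int = 10) -> MetaboliteTable:
    """Impute missing entries as the mean over the k nearest samples.

    Distance between samples is Euclidean over the metabolites both have
    observed, rescaled by the number of shared dimensions
    (scikit-learn's ``nan_euclidean`` metric).
    """
    n = len(table.sample_ids)
    if k > n - 1:
        raise ConfigurationError(f"knn k={k} exceeds n_samples-1={n - 1}")
    if table.values.isna().all(axis=0).any():
        s = table.values.columns[table.values.isna().all(axis=0)][0]
        raise DataError(f"sample {s!r} has no observed values; cannot impute")
    if not table.values.isna().any().any():
        return table._with(table.values.copy())
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # samples as rows so neighbors are samples
    imputed = imputer.fit_transform(table.values.to_numpy(float).T).T
    values = pd.DataFrame(
        imputed, index=table.values.index, columns=table.values.columns
    )
    return table._with(values)


def prepare_targeted(
    table: MetaboliteTable, config: PrepConfig = PrepConfig()
) -> tuple[MetaboliteTable, dict]:
    """Detection filters -> half-minimum zeros -> log2 -> Pareto."""
    table, rep_m = drop_undetected_metabolites(table, config.max_undetected_frac)
    table, rep_s = drop_sparse_samples(table, config.min_sample_detect_frac)
    table = replace_zeros_half_min(table)
    table = log_transform(table, config.log_base)
    table = pareto_scale(table)
    return table, {"metabolite_filter": rep_m, "sample_filter": rep_s}


def prepare_gcms(
    table: MetaboliteTable, config: PrepConfig = PrepConfig()
) -> tuple[MetaboliteTable, dict]:
    """Detection filters -> log2 -> batch mean-centering -> KNN -> Pareto."""
    table, rep_m = drop_undetected_metabolites(table, config.max_undetected_frac)
    table, rep_s = drop_sparse_samples(table, config.min_sample_detect_frac)
    n_missing = int(table.values.isna().sum().sum())
    table = replace_zeros_half_min(table)
    table = log_transform(table, config.log_base)
    table = batch_mean_center(table)
    k = min(config.knn_k, len(table.sample_ids) - 1)
    table = knn_impute(table, k)
    table = pareto_scale(table)
    return table, {
        "metabolite_filter": rep_m,
        "sample_filter": rep_s,
        "n_imputed": n_missing,
    }
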