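"""OTU count-table preprocessing for 16S amplicon surveys.

Implements the standard preprocessing chain for longitudinal infant stool
profiles: sparse-OTU and low-depth-sample filters, rarefaction by
multivariate-hypergeometric subsampling, cumulative-sum-scaling (CSS)
normalization, Shannon alpha diversity, taxonomy aggregation, and
closed-reference alignment of an external cohort onto a trimmed reference
feature set.

All operations are pure: they return new :class:`CountTable` objects and,
where samples or features are dropped, a small report dict suitable for JSON
serialization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

_RANK_INDEX = {
    "kingdom": 0,
    "phylum": 1,
    "class": 2,
    "order": 3,
    "family": 4,
    "genus": 5,
}


@dataclass
class CountTable:
    """An integer OTU-by-sample count matrix with optional taxonomy strings.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = features (OTUs or
        aggregated taxa), columns = samples.
    taxonomy
        Optional Series of rank-delimited taxonomy strings
        (``Kingdom;Phylum;Class;Order;Family;Genus``), indexed like
        ``counts.index``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataError(f"duplicate feature id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise DataError(
                    "non-integer count at feature "
                    f"{self.counts.index[bad[0]]!r}, sample "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count at feature {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
            if self.taxonomy.isna().any():
                missing = self.taxonomy.index[self.taxonomy.isna()][0]
                raise DataError(f"taxonomy missing for feature {missing!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            zero = totals.index[totals == 0][0]
            raise DataError(f"sample {zero!r} has zero total count")
        return self.counts / totals

    def select_features(self, feature_ids) -> "CountTable":
        tax = None if self.taxonomy is None else self.taxonomy.loc[feature_ids]
        return CountTable(self.counts.loc[feature_ids].copy(), tax)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)].copy(), self.taxonomy)


def read_count_table(path) -> CountTable:
    """Read a TSV count table (first column feature id, optional trailing
    ``taxonomy`` column, remaining columns integer counts per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].copy()
        df = df.drop(columns=["taxonomy"])
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-numeric count in {path}: {exc}") from exc
    return CountTable(counts, taxonomy)


def write_count_table(table: CountTable, path) -> None:
    out = table.counts.copy()
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t", index_label="feature_id")


def filter_sparse_otus(
    table: CountTable, min_count: int = 10, min_prevalence: float = 0.10
) -> CountTable:
    """Drop OTUs that do not exceed ``min_count`` reads (strictly) in at least
    ``ceil(min_prevalence * n_samples)`` samples.

    The count threshold is strict ("more than"), the prevalence threshold is
    inclusive ("at least"); both boundaries are unit-tested.
    """
    needed = math.ceil(min_prevalence * table.n_samples)
    hits = (table.counts > min_count).sum(axis=1)
    keep = table.counts.index[hits >= needed]
    if len(keep) == 0:
        warnings.warn("sparse-OTU filter removed every feature", stacklevel=2)
    return table.select_features(keep)


def filter_low_depth_samples(
    table: CountTable, min_reads: int = 50
) -> tuple[CountTable, dict]:
    """Drop samples with a column sum below ``min_reads``; report dropped ids."""
    totals = table.counts.sum(axis=0)
    dropped = [s for s in table.sample_ids if totals[s] < min_reads]
    kept = [s for s in table.sample_ids if totals[s] >= min_reads]
    report = {
        "dropped_samples": dropped,
        "reason": f"column sum < {min_reads}",
        "n_dropped": len(dropped),
    }
    return table.select_samples(kept), report


def rarefy(
    table: CountTable, depth: int = 5000, seed: int | None = 0
) -> tuple[CountTable, dict]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and reported.
    Subsampling is multivariate hypergeometric, so a sample whose total
    already equals ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ConfigurationError(f"depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    kept, dropped = [], []
    columns = {}
    for s in table.sample_ids:
        if totals[s] < depth:
            dropped.append(s)
            continue
        kept.append(s)
        col = table.counts[s].to_numpy()
        columns[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(columns, index=table.counts.index)
    counts = counts[kept] if kept else pd.DataFrame(index=table.counts.index)
    report = {
        "dropped_samples": dropped,
        "reason": f"total reads < rarefaction depth {depth}",
        "depth": depth,
    }
    return CountTable(counts.astype(np.int64), table.taxonomy), report


def css_normalize(
    table: CountTable, quantile: float = 0.5, mode: str = "fixed"
) -> tuple[pd.DataFrame, pd.Series]:
    """Cumulative-sum-scaling normalization.

    For each sample with ``m`` positive counts, the scaling factor is the sum
    of the smallest ``ceil(q * m)`` positive counts; normalized values are
    ``count / factor * 1000``.  ``mode='adaptive'`` replicates the published
    instability heuristic: it scans candidate quantiles and picks the smallest
    one at which the per-sample cumulative-sum profile starts to diverge
    (relative deviation from the median profile > 0.1).

    Returns the normalized real matrix and the per-sample scaling factors.
    """
    if not 0 < quantile <= 1:
        raise ConfigurationError(f"quantile must be in (0, 1], got {quantile}")
    arr = table.counts.to_numpy()
    if (arr.sum(axis=0) == 0).any():
        zero = table.counts.columns[arr.sum(axis=0) == 0][0]
        raise DataError(f"sample {zero!r} is all zero; cannot CSS-normalize")
    if mode == "adaptive":
        quantile = _css_adaptive_quantile(arr)
    elif mode != "fixed":
        raise ConfigurationError(f"unknown CSS mode {mode!r}")
    factors = {}
    for j, s in enumerate(table.sample_ids):
        pos = np.sort(arr[:, j][arr[:, j] > 0])
        take = math.ceil(quantile * pos.size)
        factors[s] = float(pos[:take].sum())
    factors = pd.Series(factors, name="css_factor")
    normalized = table.counts / factors * 1000.0
    return normalized, factors


def _css_adaptive_quantile(arr: np.ndarray, rel_tol: float = 0.1) -> float:
    """Smallest quantile at which per-sample scaled cumulative sums deviate
    from the median reference profile by more than ``rel_tol``."""
    grid = np.arange(1, 20) / 20.0
    profiles = []
    for j in range(arr.shape[1]):
        pos = np.sort(arr[:, j][arr[:, j] > 0]).astype(float)
        cum = np.cumsum(pos) / pos.sum()
        idx = np.minimum((np.ceil(grid * pos.size) - 1).astype(int), pos.size - 1)
        profiles.append(cum[idx])
    profiles = np.array(profiles)
    ref = np.median(profiles, axis=0)
    dev = np.median(np.abs(profiles - ref), axis=0) / np.maximum(ref, 1e-12)
    above = np.nonzero(dev > rel_tol)[0]
    if above.size == 0:
        return 0.5
    return float(grid[above[0]])


def shannon_diversity(table: CountTable) -> pd.Series:
    """Shannon index H = -sum p_i ln p_i per sample (natural log)."""
    rel = table.relative_abundance().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-terms.sum(axis=0), index=table.sample_ids, name="shannon")


def _parse_rank(taxonomy: str, rank: str, feature_id: str) -> str:
    levels = [t.strip() for t in taxonomy.split(";")]
    idx = _RANK_INDEX[rank]
    if len(levels) < _RANK_INDEX["family"] + 1 or not levels[_RANK_INDEX["family"]]:
        raise DataError(
            f"taxonomy for feature {feature_id!r} is not resolvable at the "
            f"family level: {taxonomy!r}"
        )
    if idx < len(levels) and levels[idx]:
        return levels[idx]
    # unassigned below family: pool under "<parent> unclassified"
    parent = levels[idx - 1]
    return f"{parent} unclassified"


def aggregate_taxonomy(table: CountTable, rank: str = "family") -> CountTable:
    """Sum OTU counts over shared taxonomy labels at ``rank``.

    OTUs lacking an assignment at ``rank`` are pooled under
    ``"<parent rank> unclassified"`` (e.g. ``"Enterococcaceae unclassified"``
    for a family with no genus call).  Column sums are conserved.
    """
    if rank not in ("family", "genus"):
        raise ConfigurationError(f"rank must be 'family' or 'genus', got {rank!r}")
    if table.taxonomy is None:
        raise DataError("count table has no taxonomy; cannot aggregate")
    labels = pd.Series(
        [
            _parse_rank(str(t), rank, f)
            for f, t in table.taxonomy.items()
        ],
        index=table.counts.index,
    )
    agg = table.counts.groupby(labels, sort=False).sum()
    return CountTable(agg)


def closed_reference_map(
    reference: CountTable, external: CountTable
) -> tuple[CountTable, dict]:
    """Align an external cohort's table onto the reference feature set.

    Keeps, in reference order, the reference features present in the external
    table; reports reference features the external cohort lacks; silently
    discards external-only features (closed-reference semantics).
    """
    ext_ids = set(external.feature_ids)
    shared = [f for f in reference.feature_ids if f in ext_ids]
    missing = [f for f in reference.feature_ids if f not in ext_ids]
    if not shared:
        raise DataError("no reference features present in external table")
    report = {"removed_reference_features": missing, "n_removed": len(missing)}
    return external.select_features(shared), report
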