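"""Community-structure layer: JSD, PCoA, PAM, gap statistic, associations.

Microbiota samples are compared by Jensen-Shannon divergence (natural log,
bounded by ln 2), ordinated by classical principal-coordinates analysis, and
grouped by partitioning-around-medoids (PAM, BUILD + SWAP) on the retained
ordination axes; the number of clusters is chosen by the gap statistic with
a uniform-box reference.  Cluster-level summaries relate membership to time
and growth group via per-cluster binary logistic models with infant-level
cluster-bootstrap inference, and taxa-metabolite relationships are Spearman
correlations with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise DataError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")
        if not np.isfinite(d).all() or (d < -1e-12).any():
            raise DataError("distances must be finite and nonnegative")
        self.d = d


@dataclass
class Ordination:
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    coordinates: pd.DataFrame  # samples x retained axes
    n_axes_retained: int


@dataclass
class ClusterSolution:
    assignments: pd.Series  # sample id -> cluster id (1-based)
    k: int
    medoids: list[str]
    total_cost: float
    gap_curve: pd.DataFrame | None = None  # columns: k, gap, se


def jsd_matrix(rel_abundance: pd.DataFrame, sqrt: bool = False) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence between sample compositions.

    JSD(P, Q) = H(M) - (H(P) + H(Q)) / 2 with M = (P + Q)/2, natural log;
    values lie in [0, ln 2].  ``sqrt=True`` returns the metric sqrt(JSD).
    """
    P = rel_abundance.to_numpy(dtype=float)
    if (P < 0).any():
        raise DataError("negative relative abundance")
    sums = P.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-8):
        bad = rel_abundance.columns[np.argmax(np.abs(sums - 1))]
        raise DataError(f"column {bad!r} does not sum to 1")
    n = P.shape[1]

    def entropy_cols(A: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(A > 0, A * np.log(A), 0.0)
        return -t.sum(axis=0)

    h = entropy_cols(P)
    d = np.zeros((n, n))
    for i in range(n):
        M = (P[:, i : i + 1] + P[:, i + 1 :]) / 2.0
        hm = entropy_cols(M)
        d[i, i + 1 :] = hm - (h[i] + h[i + 1 :]) / 2.0
    d = d + d.T
    d = np.clip(d, 0.0, np.log(2.0))
    if sqrt:
        d = np.sqrt(d)
    return DistanceMatrix(list(rel_abundance.columns), d)


def pcoa(dm: DistanceMatrix, retain_frac: float = 0.80) -> Ordination:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposes the double-centered -d^2/2 matrix; negative eigenvalues
    are reported but their axes discarded.  Retained axes are the leading
    positive-eigenvalue axes explaining at least ``retain_frac`` of the
    positive-eigenvalue mass ("most significant eigenvectors").
    """
    d = dm.d
    n = d.shape[0]
    B = -0.5 * d**2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(eigval.max(), 1.0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if pos.sum() == 0:
        raise DataError("no positive eigenvalues; degenerate distance matrix")
    mass = np.cumsum(eigval[pos]) / eigval[pos].sum()
    n_retain = int(np.searchsorted(mass, retain_frac) + 1)
    frame = pd.DataFrame(
        coords[:, :n_retain],
        index=dm.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(n_retain)],
    )
    return Ordination(eigenvalues=eigval, coordinates=frame, n_axes_retained=n_retain)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase; ties broken by lowest sample index."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions in nearest distance
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))  # argmax takes lowest index on ties
    return medoids


def pam_cluster(
    coordinates: pd.DataFrame | np.ndarray,
    k: int,
    seed: int | None = None,
    sample_ids=None,
    precomputed: np.ndarray | None = None,
) -> ClusterSolution:
    """Partitioning around medoids on Euclidean coordinates (or a
    precomputed dissimilarity), BUILD + best-improvement SWAP to a local
    optimum of the total within-cluster dissimilarity.

    Deterministic: BUILD and SWAP break ties toward the lowest sample index,
    so the result is invariant to a relabeling-free row permutation (``seed``
    is accepted for interface symmetry but never consumed).
    """
    if isinstance(coordinates, pd.DataFrame):
        ids = list(coordinates.index)
        X = coordinates.to_numpy(float)
    else:
        X = np.asarray(coordinates, float)
        ids = list(sample_ids) if sample_ids is not None else [
            f"S{i}" for i in range(X.shape[0])
        ]
    if precomputed is not None:
        D = np.asarray(precomputed, float)
    else:
        sq = (X**2).sum(axis=1)
        D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0))
    n = D.shape[0]
    if not 2 <= k < n:
        raise ConfigurationError(f"k must satisfy 2 <= k < n_samples, got k={k}, n={n}")

    medoids = _pam_build(D, k)
    while True:
        med = np.array(medoids)
        dist_to_med = D[:, med]  # n x k
        nearest = dist_to_med.argmin(axis=1)
        dnear = dist_to_med[np.arange(n), nearest]
        if k > 1:
            masked = dist_to_med.copy()
            masked[np.arange(n), nearest] = np.inf
            dsecond = masked.min(axis=1)
        else:
            dsecond = np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        non_medoids = [h for h in range(n) if h not in medoids]
        H = np.array(non_medoids)
        for mi in range(k):
            owned = nearest == mi
            # points owned by the removed medoid reassign to min(second, new)
            delta_owned = (
                np.minimum(D[np.ix_(owned, H)], dsecond[owned, None])
                - dnear[owned, None]
            ).sum(axis=0)
            # other points may switch to the new medoid if it is closer
            other = ~owned
            delta_other = np.minimum(
                D[np.ix_(other, H)] - dnear[other, None], 0.0
            ).sum(axis=0)
            delta = delta_owned + delta_other
            j = int(np.argmin(delta))
            if delta[j] < best_delta:
                best_delta, best_swap = float(delta[j]), (mi, int(H[j]))
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    med = np.array(sorted(medoids))
    nearest = D[:, med].argmin(axis=1)
    cost = float(D[np.arange(n), med[nearest]].sum())
    assignments = pd.Series(nearest + 1, index=ids, name="cluster")
    return ClusterSolution(
        assignments=assignments,
        k=k,
        medoids=[ids[m] for m in med],
        total_cost=cost,
    )


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum_r D_r / (2 n_r) with D_r the within-cluster sum of squared
    Euclidean distances (the gap statistic's pooled dispersion)."""
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        if len(pts) < 2:
            continue
        sq = (pts**2).sum(axis=1)
        D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * pts @ pts.T, 0.0)
        total += D2.sum() / (2.0 * len(pts))  # D2.sum() counts each pair twice
    return total


def gap_statistic(
    coordinates: pd.DataFrame | np.ndarray,
    k_range=range(1, 9),
    B: int = 50,
    seed: int = 0,
    method: str = "globalSEmax",
) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters by the gap statistic.

    Gap(k) = E*[log W_k] - log W_k with B uniform-box reference draws over
    the observed coordinate ranges.  ``method`` picks the selection rule:

    * ``"globalSEmax"`` (default): the smallest k whose gap is within one
      standard error of the global maximum of the gap curve.  Robust when
      the curve is flat (with small wiggles) below the true k and jumps
      there, as it does for well-separated clusters.
    * ``"tibshirani"``: smallest k with Gap(k) >= Gap(k+1) - se(k+1), the
      original one-step rule.  On widely separated clusters the curve can
      be flat from k=1, making this rule terminate immediately.
    """
    X = (
        coordinates.to_numpy(float)
        if isinstance(coordinates, pd.DataFrame)
        else np.asarray(coordinates, float)
    )
    if np.allclose(X, X[0]):
        raise DataError("all points identical; gap statistic undefined")
    ks = list(k_range)
    if not ks or ks[-1] >= X.shape[0]:
        raise ConfigurationError(f"k_range {ks} invalid for n={X.shape[0]}")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int) -> float:
        if k == 1:
            labels = np.zeros(data.shape[0], dtype=int)
        else:
            labels = pam_cluster(data, k).assignments.to_numpy()
        return float(np.log(_within_dispersion(data, labels)))

    log_w = np.array([log_wk(X, k) for k in ks])
    ref = np.empty((B, len(ks)))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        ref[b] = [log_wk(Xb, k) for k in ks]
    gap = ref.mean(axis=0) - log_w
    se = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    chosen = _choose_k(ks, gap, se, method)
    curve = pd.DataFrame({"k": ks, "gap": gap, "se": se})
    return chosen, curve


def _choose_k(ks, gap, se, method: str) -> int:
    if method == "tibshirani":
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                return ks[i]
        return ks[-1]
    if method != "globalSEmax":
        raise ConfigurationError(f"unknown gap selection method {method!r}")
    m = int(np.argmax(gap))
    threshold = gap[m] - se[m]
    for i in range(m + 1):
        if gap[i] >= threshold:
            return ks[i]
    return ks[m]


def cluster_group_time_association(
    assignments: pd.Series,
    metadata: pd.DataFrame,
    time_var: str = "study_week",
    group_var: str = "group",
    infant_var: str = "infant_id",
    n_boot: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster binary logistic models of membership on time + group.

    Inference respects repeated measures through an infant-level cluster
    bootstrap: infants are resampled with replacement, the model refit, and
    two-sided p-values taken as the sign-crossing fraction of the bootstrap
    coefficient distribution.  Clusters perfectly separated by a predictor
    are flagged with no estimate.
    """
    meta = metadata.loc[assignments.index]
    group_codes = (meta[group_var] == sorted(meta[group_var].unique())[-1]).astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "time": meta[time_var].astype(float),
            "group": group_codes,
        },
        index=assignments.index,
    )
    infants = meta[infant_var]
    unique_infants = infants.unique()
    rng = np.random.default_rng(seed)
    rows = []
    for c in sorted(assignments.unique()):
        y = (assignments == c).astype(float)
        if y.nunique() < 2:
            rows.append(
                {"cluster": c, "flag": "degenerate: all samples one side"}
            )
            continue
        flagged = None
        for var in ("time", "group"):
            if _separated(y, X[var]):
                flagged = f"perfect separation on {var}"
        if flagged:
            rows.append({"cluster": c, "flag": flagged})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        boot = np.full((n_boot, 2), np.nan)
        for b in range(n_boot):
            take = rng.choice(unique_infants, size=len(unique_infants), replace=True)
            idx = np.concatenate([np.flatnonzero(infants.to_numpy() == i) for i in take])
            yb, Xb = y.iloc[idx], X.iloc[idx]
            if yb.nunique() < 2:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fb = sm.Logit(yb, Xb).fit(disp=0, maxiter=100)
                boot[b] = fb.params[["time", "group"]]
            except Exception:
                continue
        row = {"cluster": c, "flag": ""}
        for j, var in enumerate(("time", "group")):
            draws = boot[:, j]
            draws = draws[np.isfinite(draws)]
            coef = float(fit.params[var])
            if draws.size < n_boot // 2:
                row[f"{var}_p"] = np.nan
            else:
                frac = min(np.mean(draws <= 0), np.mean(draws >= 0))
                row[f"{var}_p"] = float(min(1.0, 2 * max(frac, 1.0 / draws.size)))
            row[f"{var}_coef"] = coef
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def _separated(y: pd.Series, x: pd.Series) -> bool:
    """Perfect separation check: the predictor ranges of the two outcome
    classes do not overlap."""
    a, b = x[y == 1], x[y == 0]
    return a.min() > b.max() or a.max() < b.min()


def taxa_metabolite_correlations(
    taxa: pd.DataFrame, metabolites: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlations for every (taxon row, metabolite row) pair over
    shared samples, BH-adjusted across all pairs.

    Constant vectors give an undefined rho, reported as missing and excluded
    from the adjustment.
    """
    shared = [s for s in taxa.columns if s in metabolites.columns]
    if len(shared) < 8:
        raise DataError(f"need >= 8 paired samples, got {len(shared)}")
    rows = []
    for t in taxa.index:
        x = taxa.loc[t, shared].to_numpy(float)
        for m in metabolites.index:
            y = metabolites.loc[m, shared].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"taxon": t, "metabolite": m, "rho": np.nan, "p_value": np.nan})
                continue
            rho, p = spearmanr(x, y)
            rows.append({"taxon": t, "metabolite": m, "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out
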