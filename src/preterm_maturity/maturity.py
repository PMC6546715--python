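"""Random-forest "maturity age" machinery.

The same engine serves the microbiota and the metabolome: a random forest is
trained to predict postmenstrual age (PMA) from feature profiles of the
appropriate-growth reference group; cross-validation over sequentially
smaller feature sets yields a sparse model; a permutation test on shuffled
ages assesses significance; a GCV smoothing spline of predicted age against
PMA defines the reference maturation curve.  Each scored sample then gets

* predicted_age      - the forest's output ("microbiota age" / "metabolic
                       maturity age"), in weeks PMA;
* relative_maturity  - predicted_age minus the reference spline evaluated at
                       the sample's actual PMA (clamped to the spline
                       domain), in weeks;
* for_age_z          - (predicted_age - median reference predicted age in
                       the sample's PMA bin) / SD of reference predicted
                       ages in that bin (MAZ / metabolome-for-age Z), using
                       one-month bins <30, 30-33, 34-37, >=38 weeks by
                       default.

Cross-validation folds group by infant so repeated measures from one infant
never straddle a fold; forests sort samples by id internally, making every
fit invariant to input row order under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold

from .errors import ConfigurationError, DataError

_MODEL_FORMAT_VERSION = 1

DEFAULT_BINS = (30.0, 34.0, 38.0)  # interior edges of the one-month PMA bins


@dataclass
class CvCurve:
    """Held-out MSE over a descending grid of feature-subset sizes."""

    n_features_grid: list[int]
    cv_mse: list[float]
    selected_n: int


@dataclass
class PermutationResult:
    """Observed out-of-bag MSE against an age-permuted null."""

    observed_stat: float
    null_stats: list[float]
    p_value: float


@dataclass
class ForestFit:
    """A fitted forest plus its ranked importances and OOB diagnostics."""

    forest: RandomForestRegressor
    importance: pd.Series  # descending, ties broken by feature id
    oob_predictions: pd.Series
    oob_r2: float
    oob_mse: float


@dataclass
class ReferenceSpline:
    """Cubic GCV smoothing spline of predicted age vs PMA, clamped outside
    the training PMA range."""

    spline: object
    lo: float
    hi: float
    residuals: np.ndarray | None = None

    def __call__(self, pma) -> np.ndarray:
        t = np.clip(np.asarray(pma, dtype=float), self.lo, self.hi)
        return np.asarray(self.spline(t), dtype=float)


@dataclass
class MaturityModel:
    """A fitted sparse maturity model and everything needed to score samples."""

    feature_ids: list[str]
    forest: RandomForestRegressor
    n_trees: int
    importance: pd.Series
    r_squared: float
    cv_curve: CvCurve | None
    permutation: PermutationResult | None
    spline: ReferenceSpline
    reference: pd.DataFrame  # columns: pma_weeks, predicted_age (training OOB)
    bins: tuple[float, ...] = DEFAULT_BINS
    seed: int = 0


def _check_features(X: pd.DataFrame, ages) -> tuple[pd.DataFrame, pd.Series]:
    ages = pd.Series(np.asarray(ages, dtype=float), index=X.index)
    if X.isna().any().any():
        col = X.columns[X.isna().any()][0]
        raise DataError(
            f"feature {col!r} has missing values; impute during preprocessing"
        )
    if len(X) < 10:
        raise DataError(f"need >= 10 samples to fit an age model, got {len(X)}")
    return X, ages


def _ranked_importance(forest: RandomForestRegressor, columns) -> pd.Series:
    imp = pd.Series(forest.feature_importances_, index=columns)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order]


def fit_age_model(
    X: pd.DataFrame, ages, n_trees: int = 500, seed: int = 0
) -> ForestFit:
    """Fit a random-forest age regression with out-of-bag diagnostics.

    Samples are sorted by id before fitting so results do not depend on input
    row order.  Importance is impurity-based, ranked descending with
    lexicographic tie-break on feature id.
    """
    X, ages = _check_features(X, ages)
    order = X.index.sort_values()
    Xs, ys = X.loc[order], ages.loc[order]
    if float(np.std(ys)) == 0.0:
        warnings.warn("ages are constant; model has no signal", stacklevel=2)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1 / 3,  # p/3 per split, the regression convention
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        warnings.filterwarnings("ignore", message=".*invalid value.*")
        forest.fit(Xs.to_numpy(), ys.to_numpy())
        oob = np.asarray(forest.oob_prediction_, dtype=float)
    valid = ~np.isnan(oob)
    mse = float(np.mean((oob[valid] - ys.to_numpy()[valid]) ** 2))
    var = float(np.var(ys.to_numpy()[valid]))
    r2 = 1.0 - mse / var if var > 0 else float("-inf")
    return ForestFit(
        forest=forest,
        importance=_ranked_importance(forest, Xs.columns),
        oob_predictions=pd.Series(oob, index=order).reindex(X.index),
        oob_r2=r2,
        oob_mse=mse,
    )


def _feature_grid(p: int, grid_factor: float = 0.75) -> list[int]:
    """Descending grid p, ceil(factor*p), ..., 1 (always contains p and 1)."""
    grid = [p]
    while grid[-1] > 1:
        nxt = min(grid[-1] - 1, math.ceil(grid[-1] * grid_factor))
        grid.append(nxt)
    return grid


def cross_validate_feature_counts(
    X: pd.DataFrame,
    ages,
    infant_ids,
    folds: int | None = None,
    grid_factor: float = 0.75,
    n_trees: int = 500,
    select_tol: float = 0.05,
    seed: int = 0,
) -> CvCurve:
    """Infant-grouped cross-validation of feature-subset size.

    Within each fold a full forest is fit on the training split; its
    importance ranking defines the nested top-k subsets, each refit and
    evaluated on the held-out split.  ``folds`` defaults to
    ``min(100, n_infants)``; a larger request degrades to
    leave-one-infant-out with a warning.
    """
    X, ages = _check_features(X, ages)
    infants = pd.Series(list(infant_ids), index=X.index)
    n_infants = infants.nunique()
    if folds is None:
        folds = min(100, n_infants)
    if folds > n_infants:
        warnings.warn(
            f"{folds} folds exceed {n_infants} infants; using leave-one-infant-out",
            stacklevel=2,
        )
        folds = n_infants
    grid = _feature_grid(X.shape[1], grid_factor)
    sq_err = {k: [] for k in grid}
    splitter = GroupKFold(n_splits=folds)
    for fold, (tr, te) in enumerate(
        splitter.split(X.to_numpy(), groups=infants.to_numpy())
    ):
        Xtr, ytr = X.iloc[tr], ages.iloc[tr]
        Xte, yte = X.iloc[te], ages.iloc[te]
        full = RandomForestRegressor(
            n_estimators=n_trees, max_features=1 / 3,
            random_state=seed + fold, n_jobs=1,
        )
        full.fit(Xtr.to_numpy(), ytr.to_numpy())
        ranking = _ranked_importance(full, X.columns).index
        for k in grid:
            cols = list(ranking[:k])
            sub = RandomForestRegressor(
                n_estimators=n_trees, max_features=1 / 3,
                random_state=seed + fold, n_jobs=1,
            )
            sub.fit(Xtr[cols].to_numpy(), ytr.to_numpy())
            pred = sub.predict(Xte[cols].to_numpy())
            sq_err[k].append(float(np.mean((pred - yte.to_numpy()) ** 2)))
    cv_mse = [float(np.mean(sq_err[k])) for k in grid]
    curve = CvCurve(n_features_grid=grid, cv_mse=cv_mse, selected_n=grid[0])
    curve.selected_n = _select_n(curve, select_tol)
    return curve


def _select_n(cv: CvCurve, tol: float) -> int:
    best = min(cv.cv_mse)
    eligible = [
        k for k, m in zip(cv.n_features_grid, cv.cv_mse) if m <= (1 + tol) * best
    ]
    return min(eligible)


def select_sparse_features(
    cv: CvCurve, full_importance: pd.Series, tol: float = 0.05
) -> list[str]:
    """Smallest grid size whose CV-MSE is within ``tol`` of the minimum;
    returns the top features of the full-model importance ranking."""
    n = _select_n(cv, tol)
    cv.selected_n = n
    return list(full_importance.index[:n])


def permutation_test(
    X: pd.DataFrame,
    ages,
    selected_features,
    n_perm: int = 1000,
    n_trees: int = 500,
    seed: int = 0,
) -> PermutationResult:
    """Significance of the sparse fit against age-permuted refits.

    The statistic is the out-of-bag MSE of the sparse model refit on the
    permuted ages (fixed feature set); p = (1 + #{null <= observed}) /
    (1 + n_perm), so a model that beats every null gets 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    X, ages = _check_features(X, ages)
    Xs = X[list(selected_features)]
    observed = fit_age_model(Xs, ages, n_trees=n_trees, seed=seed).oob_mse
    rng = np.random.default_rng(seed)
    null = []
    for b in range(n_perm):
        perm = rng.permutation(ages.to_numpy())
        null.append(
            fit_age_model(Xs, perm, n_trees=n_trees, seed=seed + 1 + b).oob_mse
        )
    p = (1 + sum(s <= observed for s in null)) / (1 + n_perm)
    return PermutationResult(observed, null, p)


def fit_reference_spline(predicted_ages, pma) -> ReferenceSpline:
    """GCV cubic smoothing spline of predicted age against PMA.

    Duplicate PMA values are collapsed to their mean predicted age with
    multiplicity weights.  Evaluation outside the training range clamps to
    the boundary value.
    """
    pma = np.asarray(pma, dtype=float)
    pred = np.asarray(predicted_ages, dtype=float)
    xs, inverse, counts = np.unique(pma, return_inverse=True, return_counts=True)
    if xs.size < 4:
        raise DataError(
            f"need >= 4 distinct PMA values for the reference spline, got {xs.size}"
        )
    ys = np.zeros_like(xs)
    np.add.at(ys, inverse, pred)
    ys = ys / counts
    spline = make_smoothing_spline(xs, ys, w=counts.astype(float), lam=None)
    ref = ReferenceSpline(spline=spline, lo=float(xs[0]), hi=float(xs[-1]))
    ref.residuals = pred - ref(pma)
    return ref


def train_maturity_model(
    X: pd.DataFrame,
    ages,
    infant_ids,
    n_trees: int = 500,
    cv_folds: int | None = None,
    grid_factor: float = 0.75,
    select_tol: float = 0.05,
    n_perm: int = 1000,
    n_features: int | None = None,
    bins: tuple[float, ...] = DEFAULT_BINS,
    seed: int = 0,
) -> MaturityModel:
    """Full training protocol on the reference (appropriate-growth) samples.

    full fit -> cross-validated sparse feature selection -> sparse refit ->
    permutation significance -> reference spline on the sparse model's
    out-of-bag predicted ages.  Pass ``n_features`` to fix the sparse size
    without cross-validating, or ``n_perm=0`` to skip the permutation test.
    """
    X, ages = _check_features(X, ages)
    full = fit_age_model(X, ages, n_trees=n_trees, seed=seed)
    cv = None
    if n_features is None:
        cv = cross_validate_feature_counts(
            X, ages, infant_ids, folds=cv_folds, grid_factor=grid_factor,
            n_trees=n_trees, select_tol=select_tol, seed=seed,
        )
        features = select_sparse_features(cv, full.importance, tol=select_tol)
    else:
        features = list(full.importance.index[:n_features])
    sparse = fit_age_model(X[features], ages, n_trees=n_trees, seed=seed)
    perm = None
    if n_perm:
        perm = permutation_test(
            X, ages, features, n_perm=n_perm, n_trees=n_trees, seed=seed
        )
    oob = sparse.oob_predictions.dropna()
    spline = fit_reference_spline(oob.to_numpy(), ages.loc[oob.index].to_numpy())
    reference = pd.DataFrame(
        {"pma_weeks": ages.loc[oob.index], "predicted_age": oob}
    )
    return MaturityModel(
        feature_ids=features,
        forest=sparse.forest,
        n_trees=n_trees,
        importance=full.importance,
        r_squared=sparse.oob_r2,
        cv_curve=cv,
        permutation=perm,
        spline=spline,
        reference=reference,
        bins=tuple(bins),
        seed=seed,
    )


def score_maturity(
    model: MaturityModel, X: pd.DataFrame, pma, reference: bool = True
) -> pd.DataFrame:
    """Predicted age, relative maturity, and for-age Z for each sample.

    ``X`` must contain every model feature (extra columns are ignored).  The
    for-age Z reference is the model's training out-of-bag predicted ages.
    """
    missing = [f for f in model.feature_ids if f not in X.columns]
    if missing:
        raise DataError(f"features missing from input: {missing}")
    pma = pd.Series(np.asarray(pma, dtype=float), index=X.index)
    predicted = model.forest.predict(X[model.feature_ids].to_numpy())
    scores = pd.DataFrame(
        {
            "pma_weeks": pma,
            "predicted_age": predicted,
            "relative_maturity": predicted - model.spline(pma),
        },
        index=X.index,
    )
    if reference:
        scores["for_age_z"] = for_age_z(scores, model.reference, model.bins)
    return scores


def reference_scores(model: MaturityModel) -> pd.DataFrame:
    """Maturity scores for the training (reference) samples themselves,
    using their out-of-bag predicted ages.

    Scoring training samples through :func:`score_maturity` would use
    in-sample forest predictions, which track true age more tightly than
    predictions for new samples and would bias any reference-vs-other
    comparison; the out-of-bag predictions are the honest analogue.
    """
    ref = model.reference
    scores = pd.DataFrame(
        {
            "pma_weeks": ref["pma_weeks"],
            "predicted_age": ref["predicted_age"],
            "relative_maturity": (
                ref["predicted_age"].to_numpy()
                - model.spline(ref["pma_weeks"])
            ),
        },
        index=ref.index,
    )
    scores["for_age_z"] = for_age_z(scores, model.reference, model.bins)
    return scores


def _bin_index(pma: np.ndarray, bins) -> np.ndarray:
    edges = np.asarray(bins, dtype=float)
    return np.digitize(pma, edges, right=False)


def _bin_label(i: int, bins) -> str:
    edges = [-math.inf, *bins, math.inf]
    return f"[{edges[i]}, {edges[i + 1]}) weeks PMA"


def for_age_z(
    scores: pd.DataFrame,
    reference: pd.DataFrame,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> pd.Series:
    """For-age Z scores against PMA-binned reference predicted ages.

    Bins are half-open ``[low, high)`` on PMA.  z = (predicted age − median
    reference predicted age in bin) / sample SD of reference predicted ages
    in bin.  A bin with fewer than 2 reference samples, or zero spread, is an
    error naming the bin.
    """
    ref_bins = _bin_index(reference["pma_weeks"].to_numpy(float), bins)
    ref_pred = reference["predicted_age"].to_numpy(float)
    sample_bins = _bin_index(scores["pma_weeks"].to_numpy(float), bins)
    z = np.empty(len(scores))
    for i in np.unique(sample_bins):
        in_bin = ref_pred[ref_bins == i]
        if in_bin.size < 2:
            raise DataError(
                f"reference bin {_bin_label(i, bins)} has {in_bin.size} "
                "samples; need >= 2"
            )
        sd = float(np.std(in_bin, ddof=1))
        if sd == 0:
            raise DataError(
                f"reference bin {_bin_label(i, bins)} has zero spread"
            )
        sel = sample_bins == i
        z[sel] = (
            scores["predicted_age"].to_numpy(float)[sel] - np.median(in_bin)
        ) / sd
    return pd.Series(z, index=scores.index, name="for_age_z")


def save_model(model: MaturityModel, path) -> None:
    """Persist a model (versioned archive; predictions round-trip exactly)."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "model": model,
        "metadata": {
            "n_trees": model.n_trees,
            "seed": model.seed,
            "feature_ids": model.feature_ids,
            "bins": list(model.bins),
        },
    }
    joblib.dump(payload, path)


def load_model(path) -> MaturityModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted archive must not mispredict silently
        raise DataError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise DataError(f"{path} is not a maturity-model archive")
    if payload["format_version"] != _MODEL_FORMAT_VERSION:
        raise DataError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {_MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
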