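"""Cohort construction, growth classification, and contingency statistics.

Growth failure means a weight below the 3rd percentile on Fenton growth
charts at 40 weeks' postmenstrual age (percentiles are inputs; chart lookup
is out of scope).  Catch-up growth is a strictly positive change in weight
z-score between an infant's consecutive collected samples.  The Fisher exact
test is computed by exact integer hypergeometric enumeration (the
conventional two-sided definition: sum the probabilities of all tables with
the observed margins whose probability does not exceed the observed
table's), so it agrees bit-for-bit with brute-force enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ConfigurationError, DataError

COMPLICATIONS = frozenset(
    {"late_onset_sepsis", "nec_medical", "nec_surgical", "sip"}
)


@dataclass(frozen=True)
class GrowthRecord:
    """One infant's growth outcome and complication history."""

    infant_id: str
    weight_percentile_at_term: float | None
    complications: frozenset = frozenset()
    died_before_term: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.complications) - COMPLICATIONS
        if unknown:
            raise ConfigurationError(
                f"unknown complications {sorted(unknown)} for {self.infant_id}"
            )


def build_analysis_cohort(records) -> tuple[list[GrowthRecord], dict]:
    """Exclude infants who died before term; report counts."""
    records = list(records)
    if not records:
        raise DataError("no growth records")
    included = [r for r in records if not r.died_before_term]
    report = {
        "n_enrolled": len(records),
        "n_excluded_died": len(records) - len(included),
        "n_retained": len(included),
    }
    if not included:
        warnings.warn("all infants excluded; empty analysis cohort", stacklevel=2)
    return included, report


def classify_growth(record: GrowthRecord) -> str:
    """'growth_failure' iff the term weight percentile is strictly < 3."""
    p = record.weight_percentile_at_term
    if p is None or (isinstance(p, float) and np.isnan(p)):
        raise DataError(f"infant {record.infant_id} has no weight percentile")
    if not 0 <= p <= 100:
        raise DataError(f"percentile {p} out of [0, 100] for {record.infant_id}")
    return "growth_failure" if p < 3 else "appropriate"


def secondary_cohort(records) -> tuple[list[GrowthRecord], dict]:
    """Retain infants with no sepsis / NEC / intestinal-perforation history."""
    records = list(records)
    included = [r for r in records if not r.complications]
    groups = pd.Series([classify_growth(r) for r in included])
    report = {
        "n_input": len(records),
        "n_retained": len(included),
        "n_excluded": len(records) - len(included),
        "group_sizes": groups.value_counts().to_dict(),
    }
    return included, report


def catch_up_labels(samples: pd.DataFrame) -> pd.Series:
    """Per-sample catch-up flags: z_t - z_{t-1} > 0 between an infant's
    consecutive collected samples (first sample of each infant unlabeled).

    ``samples`` needs columns ``infant_id``, ``study_week``, ``weight_z``;
    the returned Series is aligned to ``samples.index`` with dtype
    ``boolean`` (pd.NA for unlabeled first samples).
    """
    for col in ("infant_id", "study_week", "weight_z"):
        if col not in samples.columns:
            raise DataError(f"samples table lacks column {col!r}")
    out = pd.Series(pd.NA, index=samples.index, dtype="boolean")
    for _, grp in samples.groupby("infant_id", sort=False):
        grp = grp.sort_values("study_week")
        dz = grp["weight_z"].diff()
        out.loc[grp.index[1:]] = (dz.iloc[1:] > 0).to_numpy()
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by exact integer hypergeometric enumeration.

    Table probabilities are compared through their integer numerators
    C(r, a) * C(N - r, c - a), so tie handling is exact (no floating-point
    gate); the p-value is the summed numerators over C(N, c).
    """
    (a, b), (c, d) = _as_2x2(table)
    n = a + b + c + d
    if n == 0:
        raise DataError("contingency table has zero grand total")
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    num_obs = comb(r, a) * comb(n - r, col - a)
    total = 0
    for x in range(lo, hi + 1):
        num = comb(r, x) * comb(n - r, col - x)
        if num <= num_obs:
            total += num
    return total / comb(n, col)


def _as_2x2(table) -> tuple[tuple[int, int], tuple[int, int]]:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise DataError("contingency counts must be nonnegative integers")
        arr = arr.astype(int)
    return (int(arr[0, 0]), int(arr[0, 1])), (int(arr[1, 0]), int(arr[1, 1]))


def contingency_stats(table) -> dict:
    """Row proportions, two-sided Fisher exact p, and the odds ratio
    (Haldane 0.5 correction when a zero cell is present)."""
    (a, b), (c, d) = _as_2x2(table)
    if a + b + c + d == 0:
        raise DataError("contingency table has zero grand total")
    p = fisher_exact_2x2([[a, b], [c, d]])
    if 0 in (a, b, c, d):
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
        odds = (a_ * d_) / (b_ * c_)
        haldane = True
    else:
        odds = (a * d) / (b * c)
        haldane = False
    return {
        "row_proportions": [
            a / (a + b) if a + b else np.nan,
            c / (c + d) if c + d else np.nan,
        ],
        "p_value": p,
        "odds_ratio": odds,
        "haldane_corrected": haldane,
    }


def cohort_summary(
    cohort: pd.DataFrame,
    group_col: str = "group",
    continuous=(),
    categorical=(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table-1-style per-variable comparison between two groups.

    Continuous variables: median (IQR) per group, Wilcoxon rank-sum p
    (p = 1 when the pooled values are constant).  Categorical variables must
    be binary; counts per group, Fisher exact p.  Rows are flagged when
    p < ``alpha``.
    """
    levels = sorted(cohort[group_col].unique())
    if len(levels) != 2:
        raise DataError(f"need exactly 2 groups, got {levels}")
    g0, g1 = (cohort[cohort[group_col] == lv] for lv in levels)
    rows = []
    for var in continuous:
        x, y = g0[var].dropna(), g1[var].dropna()
        if pd.concat([x, y]).nunique() <= 1:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                f"{levels[0]}": f"{x.median():g} ({x.quantile(.25):g}, {x.quantile(.75):g})",
                f"{levels[1]}": f"{y.median():g} ({y.quantile(.25):g}, {y.quantile(.75):g})",
                "p_value": p,
            }
        )
    for var in categorical:
        x, y = g0[var].astype(bool), g1[var].astype(bool)
        table = [[int(x.sum()), int((~x).sum())], [int(y.sum()), int((~y).sum())]]
        p = fisher_exact_2x2(table)
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                f"{levels[0]}": f"{int(x.sum())}/{len(x)}",
                f"{levels[1]}": f"{int(y.sum())}/{len(y)}",
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["significant"] = out["p_value"] < alpha
    return out


def synthetic_table1_cohort() -> list[GrowthRecord]:
    """A synthetic 60-infant cohort matching the published clinical
    marginals: 2 deaths before term; 22 appropriate-growth and 36
    growth-failure infants among the 58 analyzed; 2 appropriate-growth and
    15 growth-failure infants with >= 1 complication, leaving a 41-infant
    (20 + 21) complication-free secondary cohort.

    Individual percentiles and complication assignments are fabrications
    consistent with those printed margins, for exercising the cohort
    arithmetic; they are not patient data.
    """
    records: list[GrowthRecord] = []
    comp_cycle = sorted(COMPLICATIONS)
    # 22 appropriate growth (percentile >= 3), 2 with a complication
    for i in range(22):
        comps = frozenset({comp_cycle[i % 4]}) if i < 2 else frozenset()
        records.append(
            GrowthRecord(f"AG{i + 1:02d}", 3.0 + (i % 20), comps)
        )
    # 36 growth failure (percentile < 3), 15 with >= 1 complication
    for i in range(36):
        comps = (
            frozenset({comp_cycle[i % 4], comp_cycle[(i + 1) % 4]})
            if i < 4
            else frozenset({comp_cycle[i % 4]})
            if i < 15
            else frozenset()
        )
        records.append(GrowthRecord(f"GF{i + 1:02d}", 0.5 + 2.0 * (i % 2) / 2, comps))
    # 2 infants who died before 40 weeks' PMA (excluded before grouping)
    for i in range(2):
        records.append(GrowthRecord(f"DX{i + 1:02d}", None, died_before_term=True))
    return records


def complication_contingency(records) -> np.ndarray:
    """2x2 table of complication status (rows: any / none) against growth
    group (columns: growth_failure / appropriate)."""
    arr = np.zeros((2, 2), dtype=int)
    for r in records:
        i = 0 if r.complications else 1
        j = 0 if classify_growth(r) == "growth_failure" else 1
        arr[i, j] += 1
    return arr


def synthetic_catchup_samples(
    n_infants: int = 58, n_weeks: int = 7, n_positive: int = 84, seed: int = 0
) -> pd.DataFrame:
    """Synthetic weekly weight-z trajectories with exactly ``n_positive``
    positive between-week changes across the cohort (for exercising the
    catch-up labeling at the published sample count).  Not patient data."""
    n_deltas = n_infants * (n_weeks - 1)
    if n_positive > n_deltas:
        raise ConfigurationError(
            f"cannot plant {n_positive} positive deltas in {n_deltas}"
        )
    rng = np.random.default_rng(seed)
    signs = np.array([1] * n_positive + [-1] * (n_deltas - n_positive))
    rng.shuffle(signs)
    rows = []
    k = 0
    for i in range(n_infants):
        z = float(rng.normal(-1.0, 0.3))
        for w in range(n_weeks):
            if w > 0:
                z += signs[k] * float(rng.uniform(0.05, 0.2))
                k += 1
            rows.append(
                {
                    "sample_id": f"I{i + 1:03d}W{w}",
                    "infant_id": f"I{i + 1:03d}",
                    "study_week": w,
                    "weight_z": z,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
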