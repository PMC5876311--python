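"""Split-sample validation, Holm adjustment, and exclusion sensitivity.

The validation design: split the cleaned records into a training subset
(two-thirds of each age category, at random) and a test subset (the rest);
fit the centile model on the training subset only; count records beyond the
model's 99th/95th/5th/1st centile cutoffs in each subset; compare the
train/test proportions per centile group with a chi-square test (df = 1,
no continuity correction, Fisher's exact test optional); and adjust the
four p-values per vital with the Holm step-down procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vitalcentiles import distributions as dist
from vitalcentiles.agegrid import AGE_CATEGORIES, category_for_midpoint
from vitalcentiles.gamlss import CentileModel, predict_params
from vitalcentiles.tables import CentileTable

__all__ = [
    "CENTILE_GROUPS",
    "TRAINING", "TEST",
    "split_sample",
    "tail_cutoffs",
    "count_extremes",
    "compare_proportions",
    "holm_adjust",
    "validation_report",
    "SensitivityReport",
    "sensitivity_compare",
]

TRAINING, TEST = "training", "test"

#: centile groups in published order: (label, cutoff level, direction)
CENTILE_GROUPS = (
    (">99th", 99.0, "above"),
    (">95th", 95.0, "above"),
    ("<5th", 5.0, "below"),
    ("<1st", 1.0, "below"),
)

TRAIN_FRACTION = 2.0 / 3.0


def split_sample(strata, seed) -> np.ndarray:
    """Stratified 2/3 : 1/3 random split.

    ``strata`` is a length-n sequence of stratum labels (age categories).
    Within each stratum a random permutation sends the first
    ``floor(2n/3)`` records to training and the remainder to test.
    Deterministic for a fixed seed.
    """
    strata = np.asarray(strata)
    n = len(strata)
    if n == 0:
        raise ValueError("no records to split")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=object)
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < 3:
            raise ValueError(f"stratum {s!r} has fewer than 3 records")
        perm = rng.permutation(idx)
        k = int(np.floor(TRAIN_FRACTION * len(idx)))
        labels[perm[:k]] = TRAINING
        labels[perm[k:]] = TEST
    return labels


def tail_cutoffs(model: CentileModel) -> pd.DataFrame:
    """Unrounded model quantiles at C1/C5/C95/C99 for every age category."""
    rows = []
    for cat in AGE_CATEGORIES:
        params = predict_params(model, cat.midpoint_years)
        q = dist.quantile(params, np.array([1.0, 5.0, 95.0, 99.0]))
        if model.log_scale:
            q = np.exp(q)
        rows.append((cat.midpoint_years, *q))
    return pd.DataFrame(rows, columns=["age_midpoint", "c1", "c5", "c95", "c99"]
                        ).set_index("age_midpoint")


def count_extremes(values, ages, cutoffs: pd.DataFrame) -> dict:
    """Count records beyond each age-matched centile cutoff.

    Inequalities are strict (> for the upper groups, < for the lower), so
    a value exactly on a cutoff is not counted.  Counts nest:
    count(>99th) <= count(>95th) and count(<1st) <= count(<5th).
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape:
        raise ValueError("values and ages must have the same length")
    mids = np.array([category_for_midpoint(a).midpoint_years for a in ages])
    missing = set(np.round(mids, 9)) - set(np.round(cutoffs.index.values, 9))
    if missing:
        raise ValueError(f"no cutoffs for age midpoints: {sorted(missing)}")
    cut = cutoffs.loc[mids]
    return {
        ">99th": int(np.sum(values > cut["c99"].values)),
        ">95th": int(np.sum(values > cut["c95"].values)),
        "<5th": int(np.sum(values < cut["c5"].values)),
        "<1st": int(np.sum(values < cut["c1"].values)),
    }


def compare_proportions(train, test, *, method: str = "chi2") -> float:
    """Two-sided p-value comparing two proportions given as (k, n) pairs.

    ``method='chi2'`` is the Pearson chi-square with 1 df and no continuity
    correction; ``method='fisher'`` is Fisher's exact test.  A table with a
    zero margin yields p = 1 by convention (with a warning).
    """
    (k1, n1), (k2, n2) = train, test
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; p = 1 by convention",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    if method == "fisher":
        return float(stats.fisher_exact(table.astype(int))[1])
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def holm_adjust(raw_p) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order statistics.
    """
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def validation_report(values, ages, assignment, model: CentileModel, *,
                      method: str = "chi2") -> pd.DataFrame:
    """One vital's validation table: per centile group, train/test counts
    and percentages, raw and Holm-adjusted p (family size = 4)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    assignment = np.asarray(assignment)
    cuts = tail_cutoffs(model)
    is_train = assignment == TRAINING
    n_train, n_test = int(is_train.sum()), int((~is_train).sum())
    k_train = count_extremes(values[is_train], ages[is_train], cuts)
    k_test = count_extremes(values[~is_train], ages[~is_train], cuts)

    rows, raw_ps = [], []
    for label, _, _ in CENTILE_GROUPS:
        kt, kv = k_train[label], k_test[label]
        p = compare_proportions((kt, n_train), (kv, n_test), method=method)
        raw_ps.append(p)
        rows.append({
            "centile_group": label,
            "train_n": kt, "train_pct": 100.0 * kt / n_train,
            "test_n": kv, "test_pct": 100.0 * kv / n_test,
            "raw_p": p,
        })
    adj = holm_adjust(raw_ps)
    for row, a in zip(rows, adj):
        row["holm_p"] = float(a)
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Cellwise comparison of two rounded centile tables."""

    discrepancies: pd.DataFrame   # description, centile, value_a, value_b, diff
    n_cells: int

    @property
    def n_discrepant(self) -> int:
        return len(self.discrepancies)


def sensitivity_compare(table_a: CentileTable, table_b: CentileTable
                        ) -> SensitivityReport:
    """Compare two rounded centile tables cell by cell (the with/without-
    exclusions sensitivity design)."""
    if table_a.levels != table_b.levels:
        raise ValueError("centile tables have different centile levels")
    if not table_a.values["description"].equals(table_b.values["description"]):
        raise ValueError("centile tables have different age grids")
    cols = [c for c in table_a.values.columns if c.startswith("C")]
    recs = []
    for col in cols:
        a = table_a.values[col].values
        b = table_b.values[col].values
        for i in np.flatnonzero(a != b):
            recs.append({
                "description": table_a.values["description"].iloc[i],
                "centile": col,
                "value_a": int(a[i]), "value_b": int(b[i]),
                "diff": int(b[i] - a[i]),
            })
    disc = pd.DataFrame(recs, columns=["description", "centile",
                                       "value_a", "value_b", "diff"])
    return SensitivityReport(discrepancies=disc, n_cells=table_a.n_cells)
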