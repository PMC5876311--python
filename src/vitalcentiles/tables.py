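"""Reference-table deliverables: age-by-centile and age-by-z-score grids.

Tables are built on the fixed 40-category age grid (24 monthly + 16 yearly
midpoints) with 11 centile columns C1..C99 or 13 z-score columns from -3.0
to +3.0 in 0.5-SD steps.  Cells are vital-sign values; published cells are
rounded to integers (half away from zero), but the unrounded grid is kept
alongside for round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vitalcentiles import distributions as dist
from vitalcentiles.agegrid import AGE_CATEGORIES, category_for_midpoint
from vitalcentiles.gamlss import CentileModel, predict_params

__all__ = [
    "CENTILE_LEVELS",
    "Z_GRID",
    "CentileTable",
    "ZScoreTable",
    "make_centile_table",
    "make_zscore_table",
    "lookup_zscore",
    "round_half_away",
]

#: the 11 published centile levels
CENTILE_LEVELS = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0, 97.5, 99.0)

#: default z-score columns: -3.0 to +3.0 in 0.5 steps
Z_GRID = tuple(np.arange(-6, 7) * 0.5)


def round_half_away(x):
    """Round to nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out


def _age_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "age_years_midpoint": [c.midpoint_years for c in AGE_CATEGORIES],
        "age_units_midpoint": [c.midpoint_label for c in AGE_CATEGORIES],
        "description": [c.description for c in AGE_CATEGORIES],
    })


def _check_coverage(model: CentileModel):
    lo, hi = model.age_range
    grid_lo = AGE_CATEGORIES[0].midpoint_years
    grid_hi = AGE_CATEGORIES[-1].midpoint_years
    if lo > grid_lo + 1e-9 or hi < grid_hi - 1e-9:
        raise ValueError(
            f"model age range [{lo:.3f}, {hi:.3f}] does not cover the "
            f"reference grid [{grid_lo:.3f}, {grid_hi:.3f}]")


def _centile_label(p: float) -> str:
    return f"C{p:g}"


@dataclass
class CentileTable:
    """40 x 11 grid of vital-sign values by age category and centile."""

    values: pd.DataFrame       # integer cells, as published
    raw: pd.DataFrame          # same grid before rounding
    levels: tuple

    @property
    def n_cells(self) -> int:
        return int(self.raw.shape[0] * len(self.levels))

    def to_csv(self, path, *, rounded: bool = True):
        (self.values if rounded else self.raw).to_csv(path, index=False)


@dataclass
class ZScoreTable:
    """40 x 13 grid of vital-sign values by age category and z-score."""

    values: pd.DataFrame
    raw: pd.DataFrame
    z_grid: tuple

    def to_csv(self, path, *, rounded: bool = True):
        (self.values if rounded else self.raw).to_csv(path, index=False)


def _value_grid(model: CentileModel, probs) -> np.ndarray:
    """Quantiles (response scale) at each age midpoint x probability."""
    out = np.empty((len(AGE_CATEGORIES), len(probs)))
    for i, cat in enumerate(AGE_CATEGORIES):
        params = predict_params(model, cat.midpoint_years)
        q = dist.quantile(params, np.asarray(probs, dtype=float))
        if model.log_scale:
            q = np.exp(q)
        out[i] = q
    return out


def make_centile_table(model: CentileModel, levels=CENTILE_LEVELS) -> CentileTable:
    """Evaluate the fitted model on the 40-age x 11-centile reference grid."""
    _check_coverage(model)
    levels = tuple(float(p) for p in levels)
    grid = _value_grid(model, levels)
    meta = _age_frame()
    cols = [_centile_label(p) for p in levels]
    raw = pd.concat([meta, pd.DataFrame(grid, columns=cols)], axis=1)
    rounded = raw.copy()
    rounded[cols] = round_half_away(grid).astype(int)
    return CentileTable(values=rounded, raw=raw, levels=levels)


def make_zscore_table(model: CentileModel, z_grid=Z_GRID) -> ZScoreTable:
    """Evaluate the model at standard-normal deviates z (cell = value whose
    z-score equals z): cell(age, z) = quantile(age, 100 * Phi(z))."""
    _check_coverage(model)
    z_grid = tuple(float(z) for z in z_grid)
    probs = 100.0 * stats.norm.cdf(np.asarray(z_grid))
    grid = _value_grid(model, probs)
    meta = _age_frame()
    cols = [f"z{z:+.1f}" for z in z_grid]
    raw = pd.concat([meta, pd.DataFrame(grid, columns=cols)], axis=1)
    rounded = raw.copy()
    rounded[cols] = round_half_away(grid).astype(int)
    return ZScoreTable(values=rounded, raw=raw, z_grid=z_grid)


def lookup_zscore(model: CentileModel, age_years: float, value: float) -> float:
    """z-score of a vital-sign value for the age category containing
    ``age_years`` (the screening-tool lookup)."""
    cat = category_for_midpoint(age_years)
    params = predict_params(model, cat.midpoint_years)
    v = np.log(value) if model.log_scale else value
    return float(dist.zscore(params, v))
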