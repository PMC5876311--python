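"""Synthetic ED-encounter generator anchored to published centile tables.

The proprietary source database behind the reference tables is not
available, so this module manufactures encounter/measurement files with the
same statistical structure: per-age-category heart rates drawn from BCPE
models and respiratory rates from log-scale BCT models -- both recovered by
inverse-fitting the published 40-row centile tables shipped with the
package -- plus the age mix of the published cohort, even-digit preference
in RR, simultaneous duplicate measurements, implausible outliers, and
trauma / chronic-diagnosis exclusion flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from vitalcentiles import distributions as dist
from vitalcentiles.agegrid import AGE_CATEGORIES
from vitalcentiles.distributions import BCPE, BCT, FamilyParams

__all__ = [
    "ReferenceRow",
    "GeneratorConfig",
    "load_reference_table",
    "load_age_mix",
    "build_reference_params",
    "inject_digit_bias",
    "simulate_encounters",
]

#: centile levels of the published tables, matching the c* data columns
_LEVELS = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0, 97.5, 99.0)


@dataclass(frozen=True)
class ReferenceRow:
    """Fitted family parameters for one vital at one age category."""

    description: str
    midpoint_years: float
    params: FamilyParams
    log_scale: bool
    max_residual: float   # worst |fitted - published| centile, response scale


def _data_path(name: str):
    return resources.files("vitalcentiles.data").joinpath(name)


@lru_cache(maxsize=None)
def load_reference_table(vital: str) -> pd.DataFrame:
    """The published 40-row centile table for 'hr' or 'rr'."""
    vital = vital.lower()
    if vital not in ("hr", "rr"):
        raise ValueError("vital must be 'hr' or 'rr'")
    with resources.as_file(_data_path(f"{vital}_centiles.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=None)
def load_age_mix() -> pd.DataFrame:
    """Published cohort counts per age category (40 rows)."""
    with resources.as_file(_data_path("age_groups.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=None)
def build_reference_params(max_residual: float = 1.0) -> dict:
    """Invert both published tables into per-age FamilyParams.

    HR rows are fitted as BCPE on the raw scale, RR rows as BCT on the
    natural-log scale.  Fails loudly (naming the age row) if any row cannot
    be reproduced within ``max_residual`` units at every published centile.
    """
    out = {}
    for vital, family, log_scale in (("hr", BCPE, False), ("rr", BCT, True)):
        table = load_reference_table(vital)
        rows = []
        for cat, (_, rec) in zip(AGE_CATEGORIES, table.iterrows()):
            values = np.array([rec[f"c{p:g}".lower()] for p in _LEVELS],
                              dtype=float)
            params = dist.fit_params_to_centiles(
                list(zip(_LEVELS, values)), family=family, log_scale=log_scale)
            pred = dist.quantile(params, np.asarray(_LEVELS))
            if log_scale:
                pred = np.exp(pred)
            resid = float(np.max(np.abs(pred - values)))
            if resid > max_residual:
                raise RuntimeError(
                    f"{vital.upper()} row {rec['description']!r}: fitted "
                    f"centiles deviate by {resid:.3f} (> {max_residual})")
            rows.append(ReferenceRow(
                description=str(rec["description"]),
                midpoint_years=cat.midpoint_years,
                params=params, log_scale=log_scale, max_residual=resid))
        out[vital] = tuple(rows)
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level knobs of the synthetic generator.

    Defaults follow the published cohort: age-mix weights from the printed
    per-category counts, ~7% of encounters with duplicate simultaneous
    measurements, ~0.4% flagged trauma or chronic-diagnosis cases.
    """

    n_encounters: int = 10_000
    age_weights: tuple = ()          # empty -> published age mix
    duplicate_frac: float = 0.07
    discordant_frac: float = 0.10    # share of duplicate encounters discordant
    outlier_frac: float = 0.002
    trauma_chronic_frac: float = 0.004
    digit_bias_strength: float = 0.6
    tmp_mean: float = 37.2
    tmp_sd: float = 0.8
    tmp_bounds: tuple = (34.0, 42.0)

    def __post_init__(self):
        for name in ("duplicate_frac", "discordant_frac", "outlier_frac",
                     "trauma_chronic_frac", "digit_bias_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        if self.age_weights and (len(self.age_weights) != len(AGE_CATEGORIES)
                                 or not np.isclose(sum(self.age_weights), 1.0)):
            raise ValueError("age_weights must be 40 values summing to 1")


def _age_probabilities(config: GeneratorConfig) -> np.ndarray:
    if config.age_weights:
        return np.asarray(config.age_weights, dtype=float)
    counts = load_age_mix()["count"].to_numpy(dtype=float)
    return counts / counts.sum()


def inject_digit_bias(rr, strength: float, rng) -> np.ndarray:
    """Round RR values with even-digit preference.

    With probability ``strength`` a value is rounded to the nearest even
    integer, otherwise to the nearest integer; strength 0 is plain rounding.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr must be > 0")
    even = np.asarray(2.0 * np.round(rr / 2.0))
    plain = np.asarray(np.round(rr))
    pick_even = rng.uniform(size=rr.shape) < strength
    return np.where(pick_even, even, plain)


def simulate_encounters(config: GeneratorConfig, seed):
    """Generate one synthetic cohort.

    Returns ``(encounters, measurements)`` DataFrames in the cleaning
    module's file schema.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ref = build_reference_params()
    n = config.n_encounters

    cat_idx = rng.choice(len(AGE_CATEGORIES), size=n, p=_age_probabilities(config))

    # per-category draws from the anchored distributions
    hr = np.empty(n)
    rr = np.empty(n)
    for i in range(len(AGE_CATEGORIES)):
        mask = cat_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        hr[mask] = dist.sample(ref["hr"][i].params, k, rng)
        rr[mask] = np.exp(dist.sample(ref["rr"][i].params, k, rng))
    hr = np.round(hr)                                     # monitor convention
    rr = inject_digit_bias(rr, config.digit_bias_strength, rng)
    rr = np.maximum(rr, 1.0)
    lo, hi = config.tmp_bounds
    a, b = (lo - config.tmp_mean) / config.tmp_sd, (hi - config.tmp_mean) / config.tmp_sd
    tmp = np.round(stats.truncnorm.ppf(rng.uniform(size=n), a, b,
                                       loc=config.tmp_mean, scale=config.tmp_sd), 1)

    # implausible outliers: overwrite one vital with an out-of-range value
    is_outlier = rng.uniform(size=n) < config.outlier_frac
    which = rng.integers(0, 3, size=n)
    hr = np.where(is_outlier & (which == 0),
                  rng.choice([10.0, 320.0], size=n), hr)
    rr = np.where(is_outlier & (which == 1),
                  rng.choice([0.0, 150.0], size=n), rr)
    tmp = np.where(is_outlier & (which == 2),
                   rng.choice([25.0, 48.0], size=n), tmp)

    flagged = rng.uniform(size=n) < config.trauma_chronic_frac
    trauma = flagged & (rng.uniform(size=n) < 0.5)
    chronic = flagged & ~trauma
    sex = np.where(rng.uniform(size=n) < 0.521, "M", "F")

    cats = [AGE_CATEGORIES[i] for i in cat_idx]
    eid = np.array([f"E{k:07d}" for k in range(n)])
    encounters = pd.DataFrame({
        "encounter_id": eid,
        "age_value": [c.age_value for c in cats],
        "age_unit": [c.age_unit for c in cats],
        "sex": sex,
        "trauma_flag": trauma.astype(int),
        "chronic_dx_flag": chronic.astype(int),
    })

    # time offsets: integer minutes, max pairwise gap <= 10 so every triple
    # qualifies under the 15-min rule
    t_hr = rng.integers(0, 6, size=n)
    t_rr = t_hr + rng.integers(0, 6, size=n)
    t_tmp = rng.integers(0, 11, size=n)

    parts = [pd.DataFrame({"encounter_id": eid, "vital": v, "value": val,
                           "time_offset_min": t})
             for v, val, t in (("HR", hr, t_hr), ("RR", rr, t_rr),
                               ("TMP", tmp, t_tmp))]

    # duplicate simultaneous measurements on one vital per selected encounter
    dup = rng.uniform(size=n) < config.duplicate_frac
    dup_idx = np.flatnonzero(dup)
    if len(dup_idx):
        dvital = rng.integers(0, 3, size=len(dup_idx))
        discord = rng.uniform(size=len(dup_idx)) < config.discordant_frac
        base = {0: (hr, t_hr, 0.10), 1: (rr, t_rr, 0.10), 2: (tmp, t_tmp, 0.03)}
        drows = []
        for j, (i, dv, dc) in enumerate(zip(dup_idx, dvital, discord)):
            val, t, tol = base[int(dv)]
            v0 = val[i]
            if dc:  # exceed the tolerance by 50-100% of the limit
                delta = v0 * tol * rng.uniform(1.5, 2.0)
            else:   # stay within half the allowed range
                delta = v0 * tol * rng.uniform(0.0, 0.4)
            second = v0 + rng.choice([-1.0, 1.0]) * delta
            second = max(second, 0.1)
            name = ("HR", "RR", "TMP")[int(dv)]
            if name != "TMP":
                second = np.round(second)
            else:
                second = np.round(second, 1)
            drows.append((eid[i], name, float(second), int(t[i])))
        parts.append(pd.DataFrame(drows, columns=[
            "encounter_id", "vital", "value", "time_offset_min"]))

    measurements = (pd.concat(parts, ignore_index=True)
                    .sort_values(["encounter_id", "time_offset_min", "vital"],
                                 kind="stable")
                    .reset_index(drop=True))
    return encounters, measurements


def write_cohort(encounters: pd.DataFrame, measurements: pd.DataFrame,
                 enc_path, meas_path):
    encounters.to_csv(enc_path, index=False)
    measurements.to_csv(meas_path, index=False)
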