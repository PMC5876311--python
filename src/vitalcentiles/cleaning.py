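"""Measurement-level cleaning: one analyzable observation per encounter.

The rules, applied in order per encounter:

1. resolve simultaneous duplicate measurements (identical whole-minute
   time offset, same vital) by averaging, provided the range does not
   exceed 10% of the largest value for HR/RR or 3% for TMP -- otherwise
   the encounter is discarded as discordant;
2. require an initial (HR, RR, TMP) triple taken within 15 min of one
   another (earliest qualifying triple, judged by its latest member);
3. discard implausible values (HR < 30 or > 300 bpm; RR = 0 or >= 120
   breaths/min; TMP < 30 or > 46 C) and trauma-center or chronic
   heart/respiratory-diagnosis encounters.

Every input encounter receives exactly one disposition in the exclusion log.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from vitalcentiles.agegrid import age_midpoint

__all__ = [
    "HR", "RR", "TMP", "VITALS",
    "MeasurementRecord", "EncounterRecord", "CleanObservation",
    "KEPT", "REASONS",
    "age_midpoint",
    "resolve_simultaneous",
    "assemble_initial_vitals",
    "apply_exclusions",
    "clean_encounters",
    "read_encounters", "read_measurements",
]

HR, RR, TMP = "HR", "RR", "TMP"
VITALS = (HR, RR, TMP)

#: duplicate-range tolerance as a fraction of the largest simultaneous value
RANGE_TOLERANCE = {HR: 0.10, RR: 0.10, TMP: 0.03}

#: maximum pairwise gap (minutes) within the initial vital-sign triple
TRIPLE_WINDOW_MIN = 15.0

KEPT = "kept"
REASONS = ("missing_vital", "not_within_15min", "discordant_duplicates",
           "extreme_value", "trauma", "chronic_dx")


@dataclass(frozen=True)
class MeasurementRecord:
    encounter_id: str
    vital: str
    value: float
    time_offset: float  # minutes from encounter start

    def __post_init__(self):
        if self.vital not in VITALS:
            raise ValueError(f"unknown vital {self.vital!r}")
        if not np.isfinite(self.value):
            raise ValueError("measurement value must be finite")
        if self.value < 0:
            raise ValueError("negative measurement value")
        if self.time_offset < 0:
            raise ValueError("time_offset must be >= 0")


@dataclass(frozen=True)
class EncounterRecord:
    encounter_id: str
    age_value: int
    age_unit: str
    sex: str = ""
    trauma_flag: bool = False
    chronic_dx_flag: bool = False


@dataclass(frozen=True)
class CleanObservation:
    encounter_id: str
    age_midpoint: float
    hr: float
    rr: float
    tmp: float


def resolve_simultaneous(values: Sequence[float], vital: str):
    """Resolve measurements of one vital recorded at the same date/time.

    Returns ``(value, False)`` -- the single value or the arithmetic mean --
    or ``(nan, True)`` when the range of simultaneous values exceeds the
    vital's tolerance (10% of the largest value for HR/RR, 3% for TMP).
    """
    if vital not in VITALS:
        raise ValueError(f"unknown vital {vital!r}")
    values = list(values)
    if not values:
        raise ValueError("empty value list")
    if len(values) == 1:
        return float(values[0]), False
    vmax, vmin = max(values), min(values)
    if vmax - vmin > RANGE_TOLERANCE[vital] * vmax:
        return float("nan"), True
    return float(np.mean(values)), False


def assemble_initial_vitals(measurements: Iterable[MeasurementRecord]):
    """Select the initial (HR, RR, TMP) triple taken within 15 minutes.

    Measurements at the same whole-minute offset are first resolved by
    :func:`resolve_simultaneous`; any discordant group fails the whole
    encounter.  Among qualifying triples the earliest -- by the latest
    member's time offset, ties by input order -- wins.

    Returns ``(hr, rr, tmp)`` on success, or the string reason
    (``'discordant_duplicates'``, ``'missing_vital'``, ``'not_within_15min'``)
    on failure.
    """
    by_vital: dict[str, dict[float, list[float]]] = {v: {} for v in VITALS}
    for m in measurements:
        t = round(m.time_offset)  # source grain is whole minutes
        by_vital[m.vital].setdefault(t, []).append(m.value)

    resolved: dict[str, list[tuple[float, float]]] = {}
    for vital, groups in by_vital.items():
        out = []
        for t in sorted(groups):
            value, discordant = resolve_simultaneous(groups[t], vital)
            if discordant:
                return "discordant_duplicates"
            out.append((t, value))
        resolved[vital] = out

    if any(not resolved[v] for v in VITALS):
        return "missing_vital"

    best = None  # (latest_time, hr, rr, tmp)
    for (th, vh), (tr, vr), (tt, vt) in product(*(resolved[v] for v in VITALS)):
        times = (th, tr, tt)
        if max(times) - min(times) <= TRIPLE_WINDOW_MIN:
            key = max(times)
            if best is None or key < best[0]:
                best = (key, vh, vr, vt)
    if best is None:
        return "not_within_15min"
    return best[1], best[2], best[3]


def apply_exclusions(encounter: EncounterRecord, vitals: tuple):
    """Apply the implausible-value and flag exclusions to an assembled triple.

    Returns ``(CleanObservation, 'kept')`` or ``(None, reason)`` with the
    first matching reason.  Boundary semantics are strict: HR of exactly 30
    or 300 is kept; RR of exactly 120 is dropped.
    """
    hr, rr, tmp = vitals
    if hr < 30 or hr > 300 or rr <= 0 or rr >= 120 or tmp < 30 or tmp > 46:
        return None, "extreme_value"
    if encounter.trauma_flag:
        return None, "trauma"
    if encounter.chronic_dx_flag:
        return None, "chronic_dx"
    obs = CleanObservation(
        encounter_id=encounter.encounter_id,
        age_midpoint=age_midpoint(encounter.age_value, encounter.age_unit),
        hr=hr, rr=rr, tmp=tmp,
    )
    return obs, KEPT


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def _clean_one(enc: EncounterRecord, meas: list[MeasurementRecord]):
    triple = assemble_initial_vitals(meas)
    if isinstance(triple, str):
        return None, triple
    return apply_exclusions(enc, triple)


def clean_encounters(encounters: pd.DataFrame, measurements: pd.DataFrame):
    """Clean a full cohort.

    Parameters
    ----------
    encounters : DataFrame with columns encounter_id, age_value, age_unit,
        sex, trauma_flag, chronic_dx_flag.
    measurements : DataFrame with columns encounter_id, vital, value,
        time_offset_min.

    Returns
    -------
    (clean, log) : two DataFrames.  ``clean`` has one row per kept encounter
    (encounter_id, age_midpoint, hr, rr, tmp); ``log`` has one row per input
    encounter (encounter_id, disposition, reason) -- conservation holds by
    construction.
    """
    enc = encounters.reset_index(drop=True)
    if enc["encounter_id"].duplicated().any():
        raise ValueError("duplicate encounter_id in encounters table")
    if (measurements["value"] < 0).any():
        raise ValueError("negative measurement values")

    meas = measurements.copy()
    meas["time_offset_min"] = meas["time_offset_min"].round()

    # fast path: exactly one measurement per vital (the overwhelming case)
    sizes = meas.groupby(["encounter_id", "vital"]).size().unstack(fill_value=0)
    for v in VITALS:
        if v not in sizes.columns:
            sizes[v] = 0
    simple_mask = (sizes[list(VITALS)] == 1).all(axis=1) & (
        sizes.sum(axis=1) == 3)
    simple_ids = set(sizes.index[simple_mask])

    is_simple = meas["encounter_id"].map(simple_ids.__contains__)
    wide_v = meas[is_simple].pivot(index="encounter_id", columns="vital",
                                   values="value")
    wide_t = meas[is_simple].pivot(index="encounter_id", columns="vital",
                                   values="time_offset_min")

    enc_idx = enc.set_index("encounter_id")
    # vectorized category midpoints (validity checked per category)
    for val, unit in set(zip(enc_idx["age_value"], enc_idx["age_unit"])):
        age_midpoint(int(val), str(unit))
    av = enc_idx["age_value"].astype(int)
    midpoints = pd.Series(
        np.where(enc_idx["age_unit"] == "months", (av + 0.5) / 12.0, av + 0.5),
        index=enc_idx.index)
    trauma = enc_idx.get("trauma_flag", pd.Series(0, index=enc_idx.index))
    chronic = enc_idx.get("chronic_dx_flag", pd.Series(0, index=enc_idx.index))

    reasons = pd.Series("", index=enc_idx.index, dtype=object)

    present = enc_idx.index.isin(meas["encounter_id"].unique())
    reasons[~present] = "missing_vital"

    # vectorized dispositions for the simple encounters
    sid = wide_v.index
    gap = wide_t.max(axis=1) - wide_t.min(axis=1)
    hr_v, rr_v, tmp_v = wide_v[HR], wide_v[RR], wide_v[TMP]
    extreme = ((hr_v < 30) | (hr_v > 300) | (rr_v <= 0) | (rr_v >= 120)
               | (tmp_v < 30) | (tmp_v > 46))
    r = pd.Series(KEPT, index=sid, dtype=object)
    r[chronic.loc[sid].astype(int) == 1] = "chronic_dx"
    r[trauma.loc[sid].astype(int) == 1] = "trauma"
    r[extreme] = "extreme_value"
    r[gap > TRIPLE_WINDOW_MIN] = "not_within_15min"
    reasons.loc[sid] = r

    # slow path: everything with duplicates / extra or missing measurements
    kept_complex_rows = []
    complex_ids = set(enc_idx.index[present]) - simple_ids
    if complex_ids:
        sub = meas[meas["encounter_id"].isin(complex_ids)]
        for eid, grp in sub.groupby("encounter_id", sort=False):
            row = enc_idx.loc[eid]
            e = EncounterRecord(
                encounter_id=eid,
                age_value=int(row["age_value"]),
                age_unit=str(row["age_unit"]),
                sex=str(row.get("sex", "")),
                trauma_flag=bool(int(row.get("trauma_flag", 0))),
                chronic_dx_flag=bool(int(row.get("chronic_dx_flag", 0))),
            )
            recs = [MeasurementRecord(eid, v, float(val), float(t))
                    for v, val, t in zip(grp["vital"], grp["value"],
                                         grp["time_offset_min"])]
            obs, reason = _clean_one(e, recs)
            reasons.loc[eid] = KEPT if obs is not None else reason
            if obs is not None:
                kept_complex_rows.append((eid, obs.age_midpoint,
                                          obs.hr, obs.rr, obs.tmp))

    kept = reasons == KEPT
    kept_simple = wide_v[(r == KEPT).values]

    simple_clean = pd.DataFrame({
        "encounter_id": kept_simple.index,
        "age_midpoint": midpoints.loc[kept_simple.index].values,
        "hr": kept_simple[HR].values,
        "rr": kept_simple[RR].values,
        "tmp": kept_simple[TMP].values,
    })
    complex_clean = pd.DataFrame(kept_complex_rows, columns=[
        "encounter_id", "age_midpoint", "hr", "rr", "tmp"])
    frames = [f for f in (simple_clean, complex_clean) if len(f)]
    clean = (pd.concat(frames, ignore_index=True) if frames
             else simple_clean)
    # restore input encounter order
    order = {e: i for i, e in enumerate(enc["encounter_id"])}
    clean = (clean.assign(_o=clean["encounter_id"].map(order))
             .sort_values("_o").drop(columns="_o").reset_index(drop=True))

    log = pd.DataFrame({
        "encounter_id": enc["encounter_id"],
        "disposition": np.where(kept.loc[enc["encounter_id"]].values,
                                KEPT, "dropped"),
        "reason": reasons.loc[enc["encounter_id"]].where(~kept.loc[
            enc["encounter_id"]].values, "").values,
    })
    return clean, log


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str})
    required = {"encounter_id", "age_value", "age_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"encounters file missing columns: {sorted(missing)}")
    return df


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str})
    required = {"encounter_id", "vital", "value", "time_offset_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements file missing columns: {sorted(missing)}")
    return df
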