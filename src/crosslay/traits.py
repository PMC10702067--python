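"""Derivation of egg-laying phenotypes from raw records.

Turns daily lay records (day-of-age of each egg, optional oviposition clock
time) and per-egg measurements into the analysis traits: age at first egg,
cumulative egg numbers, clutch statistics, oviposition period, first-egg
weight, egg shape index and shell/yolk ratios.

Conventions ("till X weeks of age" etc.):

* a window "till week X" includes all days of age <= 7 * X;
* a clutch is a maximal run of consecutive laying days; the number of
  pauses is the number of clutches minus one;
* average clutch length = eggs in window / number of clutches, average
  pause length = non-laying days strictly between the first and last
  clutch / number of pauses (missing when there is a single clutch);
* the oviposition period averages (24 h + clock difference) over pairs of
  lays on consecutive calendar days inside the 31-33 weeks-of-age window;
  pairs separated by a pause day are excluded;
* shape index and the shell/yolk ratios are reported on a 0-100 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import LayRecords

__all__ = [
    "age_at_first_egg",
    "cumulative_egg_number",
    "detect_clutches",
    "oviposition_period",
    "first_egg_weight",
    "egg_quality_derived",
    "derive_production_traits",
    "derive_measurement_traits",
]

PRODUCTION_WEEKS = (43, 72, 100)
OVIPOSITION_WINDOW_WEEKS = (31, 33)


# ---------------------------------------------------------------------- #
def age_at_first_egg(days: np.ndarray) -> float:
    """Day-of-age of the first lay; NaN (non-layer) when there is none."""
    days = np.asarray(days)
    return float(days.min()) if days.size else np.nan


def cumulative_egg_number(days: np.ndarray, until_week: int) -> int:
    """Number of eggs laid on days of age <= 7 * until_week."""
    if until_week <= 0:
        raise ValueError("until_week must be positive")
    days = np.asarray(days)
    return int(np.sum(days <= 7 * until_week))


def detect_clutches(days: np.ndarray, until_week: int) -> dict:
    """Clutch statistics inside the window up to ``until_week``.

    Returns number of clutches (NC), average clutch length (ACL = eggs /
    NC) and average pause length (APL = pause days between first and last
    clutch / (NC - 1); NaN when NC <= 1).  NC * ACL equals the egg count
    by construction.
    """
    days = np.sort(np.asarray(days))
    days = days[days <= 7 * until_week]
    if days.size == 0:
        return {"n_clutches": 0, "avg_clutch_length": np.nan, "avg_pause_length": np.nan}
    gaps = np.diff(days)
    n_clutches = 1 + int(np.sum(gaps > 1))
    acl = days.size / n_clutches
    if n_clutches == 1:
        apl = np.nan
    else:
        pause_days = int((days[-1] - days[0] + 1) - days.size)
        apl = pause_days / (n_clutches - 1)
    return {
        "n_clutches": n_clutches,
        "avg_clutch_length": acl,
        "avg_pause_length": apl,
    }


def oviposition_period(
    days: np.ndarray,
    times_h: np.ndarray,
    window_weeks: tuple[int, int] = OVIPOSITION_WINDOW_WEEKS,
) -> float:
    """Mean interval (hours) between successive lays on consecutive days.

    Uses lays from the beginning of ``window_weeks[0]`` to the end of
    ``window_weeks[1]`` weeks of age.  For each pair of lays on consecutive
    calendar days the interval is 24 h + (time of second - time of first);
    pairs straddling a pause day are excluded.  NaN when no usable pair.
    """
    days = np.asarray(days)
    times_h = np.asarray(times_h, dtype=float)
    lo = 7 * (window_weeks[0] - 1) + 1
    hi = 7 * window_weeks[1]
    m = (days >= lo) & (days <= hi) & np.isfinite(times_h)
    days, times_h = days[m], times_h[m]
    order = np.argsort(days)
    days, times_h = days[order], times_h[order]
    if days.size < 2:
        return np.nan
    consec = np.diff(days) == 1
    if not consec.any():
        return np.nan
    intervals = 24.0 + np.diff(times_h)[consec]
    return float(np.mean(intervals))


# ---------------------------------------------------------------------- #
def first_egg_weight(weights: np.ndarray) -> float:
    """Mean weight of the chronologically first three eggs; NaN if < 3."""
    weights = np.asarray(weights, dtype=float)
    weights = weights[np.isfinite(weights)]
    if weights.size < 3:
        return np.nan
    return float(np.mean(weights[:3]))


def egg_quality_derived(
    width: float, length: float, shell_weight: float, yolk_weight: float,
    egg_weight: float,
) -> dict:
    """Shape index and shell/yolk ratios on a 0-100 scale.

    shape index = 100 * width / length; shell ratio = 100 * shell weight /
    egg weight; yolk ratio = 100 * yolk weight / egg weight.  Ratios with a
    non-positive denominator come back NaN.
    """
    def ratio(num, den):
        if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
            return np.nan
        return 100.0 * num / den

    return {
        "shape_index": ratio(width, length),
        "shell_ratio": ratio(shell_weight, egg_weight),
        "yolk_ratio": ratio(yolk_weight, egg_weight),
    }


# ---------------------------------------------------------------------- #
def derive_production_traits(
    lay: LayRecords,
    weeks: tuple[int, ...] = PRODUCTION_WEEKS,
    oviposition_window: tuple[int, int] = OVIPOSITION_WINDOW_WEEKS,
) -> pd.DataFrame:
    """Long-format trait table of egg-production traits for every hen.

    Traits: AFE, OP, and per window week X: ENX, NCX, ACLX, APLX.  Hens
    with no eggs at all get a NaN AFE row (flagged downstream as
    non-layers); rack levels are joined from the hen table when present.
    """
    rec = lay.records
    hens = lay.hens.set_index("hen")
    days_by = {h: g["day"].to_numpy() for h, g in rec.groupby("hen", sort=False)}
    times_by = {h: g["time_h"].to_numpy() for h, g in rec.groupby("hen", sort=False)}
    rows = []

    def add(hen, trait, age, value):
        info = hens.loc[hen]
        rows.append(
            {
                "hen": hen,
                "group": info["group"],
                "rack": info.get("rack", np.nan),
                "trait": trait,
                "age": age,
                "value": value,
            }
        )

    for hen in hens.index:
        days = days_by.get(hen, np.array([], dtype=int))
        add(hen, "AFE", "single", age_at_first_egg(days))
        times = times_by.get(hen, np.array([]))
        add(hen, "OP", "single", oviposition_period(days, times, oviposition_window))
        for w in weeks:
            add(hen, f"EN{w}", str(w), float(cumulative_egg_number(days, w)))
            cl = detect_clutches(days, w)
            add(hen, f"NC{w}", str(w), float(cl["n_clutches"]))
            add(hen, f"ACL{w}", str(w), cl["avg_clutch_length"])
            add(hen, f"APL{w}", str(w), cl["avg_pause_length"])
    return pd.DataFrame(rows)


def derive_measurement_traits(
    measurements: pd.DataFrame, hens: pd.DataFrame
) -> pd.DataFrame:
    """Trait table from per-egg measurements.

    Produces FEWt (mean of the first three egg weights, rows with
    ``age_weeks == 'first'``) and, per measured age, EWt, ESI, ESR and YR.
    One record per egg for the age-specific traits (repeated records feed
    the permanent-environment models); FEWt is a single record per hen.
    """
    hens = hens.set_index("hen")
    rows = []

    def add(hen, trait, age, value):
        info = hens.loc[hen]
        rows.append(
            {
                "hen": hen,
                "group": info["group"],
                "rack": info.get("rack", np.nan),
                "trait": trait,
                "age": age,
                "value": value,
            }
        )

    firsts = measurements[measurements["age_weeks"] == "first"]
    for hen, sub in firsts.groupby("hen", sort=False):
        add(hen, "FEWt", "first", first_egg_weight(sub["egg_weight"].to_numpy()))
    aged = measurements[measurements["age_weeks"] != "first"]
    for (hen, age), sub in aged.groupby(["hen", "age_weeks"], sort=False):
        for _, egg in sub.iterrows():
            if np.isfinite(egg.get("egg_weight", np.nan)):
                add(hen, f"EWt{age}", str(age), float(egg["egg_weight"]))
            q = egg_quality_derived(
                egg.get("width", np.nan),
                egg.get("length", np.nan),
                egg.get("shell_weight", np.nan),
                egg.get("yolk_weight", np.nan),
                egg.get("egg_weight", np.nan),
            )
            if np.isfinite(q["shape_index"]):
                add(hen, f"ESI{age}", str(age), q["shape_index"])
            if np.isfinite(q["shell_ratio"]):
                add(hen, f"ESR{age}", str(age), q["shell_ratio"])
            if np.isfinite(q["yolk_ratio"]):
                add(hen, f"YR{age}", str(age), q["yolk_ratio"])
    return pd.DataFrame(rows)
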