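"""Extra-territorial excursion (ETE) detection and monthly assessment.

A badger-night spans the evening and following small hours: fixes taken at
22:00 and 23:00 belong to the same night as the 01:00 and 02:00 fixes that
follow them. Per night, the fix farthest outside the home territory is
retained; if it lies strictly more than the GPS-accuracy threshold (15 m)
beyond the boundary the night counts as one ETE. Monthly records then
carry the ETE frequency fETE = ETE nights / active collar nights, a
proportion in [0, 1] (one ETE in a 31-night month gives 0.032; an ETE
every night gives 1.0).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import TerritoryMap, distances_beyond_boundary

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_M = 15.0
NIGHT_START_HOUR = 18
NIGHT_END_HOUR = 6

ETE_COLUMNS = [
    "animal_id", "group_id", "night_date", "year", "month",
    "timestamp", "x", "y", "distance_m",
]

COHORT_JUVENILE = "Juvenile"
COHORT_YOUNG_ADULT = "YoungAdult"
COHORT_OLDER_ADULT = "OlderAdult"


class MissingTerritoryError(KeyError):
    """A fix's home group has no polygon for its year."""


def assign_nights(
    fixes: pd.DataFrame,
    night_start_hour: int = NIGHT_START_HOUR,
    night_end_hour: int = NIGHT_END_HOUR,
    *,
    on_outside: str = "drop",
) -> pd.DataFrame:
    """Attach a ``night_date`` to every fix.

    Fixes from ``night_start_hour`` to 23:59 get the calendar date of the
    evening; fixes from 00:00 through ``night_end_hour`` get the previous
    date (they belong to the night that began the evening before). Fixes
    outside both windows are dropped with a warning, or rejected when
    ``on_outside='error'``.
    """
    if not (0 <= night_end_hour < night_start_hour <= 23):
        raise ValueError("need night_start_hour > night_end_hour (night spans midnight)")
    if on_outside not in ("drop", "error"):
        raise ValueError("on_outside must be 'drop' or 'error'")
    out = fixes.copy()
    ts = pd.to_datetime(out["timestamp"])
    hour = ts.dt.hour
    evening = hour >= night_start_hour
    morning = hour <= night_end_hour
    outside = ~(evening | morning)
    if outside.any():
        n_bad = int(outside.sum())
        if on_outside == "error":
            raise ValueError(f"{n_bad} fixes fall outside the night window")
        logger.warning("dropping %d fixes outside the %02d:00-%02d:00 night window",
                       n_bad, night_start_hour, night_end_hour)
        out = out.loc[~outside]
        ts = ts.loc[~outside]
        evening = evening.loc[~outside]
    night = ts.dt.normalize() - pd.to_timedelta((~evening).astype(int), unit="D")
    out = out.assign(night_date=night.dt.date)
    return out


def detect_etes(
    fixes: pd.DataFrame,
    territory_maps: dict[int, TerritoryMap] | TerritoryMap,
    threshold_m: float = DEFAULT_THRESHOLD_M,
) -> pd.DataFrame:
    """Reduce night-assigned fixes to at most one ETE event per badger-night.

    For each fix the distance beyond the home group's territory boundary
    (for the night's year) is computed; per badger-night only the farthest
    fix is retained, and the night is an ETE iff that distance is strictly
    greater than ``threshold_m``. Distance ties are broken by earliest fix.

    ``territory_maps`` is either a dict keyed by year (fixes are scored
    against their own night-year's map) or a single TerritoryMap asserted
    to hold for the whole record.

    Returns a table with one row per ETE night (columns ``ETE_COLUMNS``).
    """
    single_map = territory_maps if isinstance(territory_maps, TerritoryMap) else None
    if "night_date" not in fixes.columns:
        raise ValueError("fixes must be night-assigned first (assign_nights)")
    if fixes.empty:
        return pd.DataFrame(columns=ETE_COLUMNS)

    df = fixes.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    night = pd.to_datetime(df["night_date"])
    df["year"] = night.dt.year
    df["month"] = night.dt.month

    missing: dict[str, set] = {}
    dist = np.full(len(df), np.nan)
    for (year, gid), idx in df.groupby(["year", "group_id"], sort=False).groups.items():
        tmap = single_map if single_map is not None else territory_maps.get(year)
        if tmap is None or gid not in tmap:
            for aid, nd in df.loc[idx, ["animal_id", "night_date"]].itertuples(index=False):
                missing.setdefault(str(aid), set()).add(nd)
            continue
        dist[df.index.get_indexer(idx)] = distances_beyond_boundary(
            df.loc[idx, ["x", "y"]].to_numpy(), tmap[gid]
        )
    if missing:
        detail = "; ".join(
            f"{aid}: {len(nights)} nights" for aid, nights in sorted(missing.items())
        )
        raise MissingTerritoryError(
            f"no territory polygon for the home group/year of some fixes ({detail})"
        )
    df["distance_m"] = dist

    # farthest fix per night; ties -> earliest timestamp
    df = df.sort_values(["animal_id", "night_date", "timestamp"], kind="stable")
    order = df.sort_values(
        ["animal_id", "night_date", "distance_m", "timestamp"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    retained = order.groupby(["animal_id", "night_date"], sort=True).head(1)
    events = retained.loc[retained["distance_m"] > threshold_m, ETE_COLUMNS]
    return events.reset_index(drop=True)


def count_active_nights(fixes: pd.DataFrame) -> pd.DataFrame:
    """Distinct nights with >= 1 fix, per animal-month.

    A night's month is the month of its ``night_date`` (the evening the
    night began), so fixes recorded at 01:00 on 1 March belong to the
    night of 28 February and count in February.
    """
    if "night_date" not in fixes.columns:
        raise ValueError("fixes must be night-assigned first (assign_nights)")
    df = fixes[["animal_id", "night_date"]].drop_duplicates()
    night = pd.to_datetime(df["night_date"])
    df = df.assign(year=night.dt.year, month=night.dt.month)
    out = (
        df.groupby(["animal_id", "year", "month"], as_index=False)
        .size()
        .rename(columns={"size": "active_nights"})
    )
    return out


def age_cohort(age_years: float) -> str:
    """Juvenile (0-1), YoungAdult (2-3), OlderAdult (>3)."""
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    if age_years <= 1:
        return COHORT_JUVENILE
    if age_years <= 3:
        return COHORT_YOUNG_ADULT
    return COHORT_OLDER_ADULT


def apply_exclusions(night_table: pd.DataFrame, exclusions: pd.DataFrame | None) -> pd.DataFrame:
    """Drop rows whose night_date falls in an excluded animal-period.

    ``exclusions`` carries animal_id, start_date, end_date (inclusive):
    periods during which an animal was a super-ranger or actively
    dispersing, when 'home' is undefined and excursions cannot be scored.
    """
    if exclusions is None or exclusions.empty:
        return night_table
    out = night_table
    nd = pd.to_datetime(out["night_date"])
    keep = pd.Series(True, index=out.index)
    for row in exclusions.itertuples(index=False):
        start = pd.to_datetime(row.start_date)
        end = pd.to_datetime(row.end_date)
        keep &= ~((out["animal_id"] == row.animal_id) & (nd >= start) & (nd <= end))
    return out.loc[keep]


def assemble_monthly(
    etes: pd.DataFrame,
    active_nights: pd.DataFrame,
    metadata: pd.DataFrame,
    exclusions: pd.DataFrame | None = None,
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """One record per collared badger-month with at least one active night.

    Zero-ETE months are retained with fETE = 0 and empty distance stats —
    they are real observations of absent excursion behaviour, and the
    frequency dataset is zero-inflated because of them. Months fully
    excluded (dispersal / super-ranging) produce no row.
    """
    nights = exclude_months(active_nights, exclusions)
    if not etes.empty:
        etes = apply_exclusions(etes, exclusions)

    if etes.empty:
        agg = pd.DataFrame(columns=["animal_id", "year", "month", "ete_count",
                                    "max_distance_m", "median_distance_m", "mean_distance_m"])
    else:
        agg = (
            etes.groupby(["animal_id", "year", "month"], as_index=False)
            .agg(
                ete_count=("distance_m", "size"),
                max_distance_m=("distance_m", "max"),
                median_distance_m=("distance_m", "median"),
                mean_distance_m=("distance_m", "mean"),
            )
        )
    monthly = nights.merge(agg, on=["animal_id", "year", "month"], how="left")
    monthly["ete_count"] = pd.to_numeric(monthly["ete_count"]).fillna(0).astype(int)
    monthly = monthly.loc[monthly["active_nights"] > 0].copy()
    monthly["fete"] = monthly["ete_count"] / monthly["active_nights"]

    meta = metadata.set_index("animal_id")
    groups, sexes, ages, cohorts, breeding = [], [], [], [], []
    for aid, yr in zip(monthly["animal_id"], monthly["year"]):
        if aid not in meta.index:
            msg = f"animal {aid!r} missing from metadata"
            if strict:
                raise KeyError(msg)
            logger.warning("%s; cohort set to unknown", msg)
            groups.append("unknown"); sexes.append("unknown"); ages.append(np.nan)
            cohorts.append("unknown"); breeding.append("unknown")
            continue
        row = meta.loc[aid]
        age = int(yr) - int(row["birth_year"])
        groups.append(row.get("group_id", "unknown"))
        sexes.append(row["sex"])
        ages.append(age)
        cohorts.append(age_cohort(age))
        breeding.append(row.get("breeding_status", "unknown"))
    monthly["group_id"] = groups
    monthly["sex"] = sexes
    monthly["age_years"] = ages
    monthly["age_cohort"] = cohorts
    monthly["breeding_status"] = breeding
    return monthly.reset_index(drop=True)


def exclude_months(active_nights: pd.DataFrame, exclusions: pd.DataFrame | None) -> pd.DataFrame:
    """Drop animal-months that overlap an exclusion period at all.

    Active-night counts are monthly, so exclusion is applied at month
    granularity: any overlap between the calendar month and the period
    removes the record (a partially dispersing month has no usable 'home').
    """
    if exclusions is None or exclusions.empty:
        return active_nights
    out = active_nights
    month_start = pd.to_datetime(dict(year=out["year"], month=out["month"], day=1))
    month_end = month_start + pd.offsets.MonthEnd(0)
    keep = pd.Series(True, index=out.index)
    for row in exclusions.itertuples(index=False):
        start = pd.to_datetime(row.start_date)
        end = pd.to_datetime(row.end_date)
        keep &= ~((out["animal_id"] == row.animal_id) & (month_start <= end) & (month_end >= start))
    return out.loc[keep]
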