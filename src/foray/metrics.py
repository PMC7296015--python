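"""Excursion effort metrics and cohort summaries.

The 'investment' metric combines how often a badger leaves its territory
with how far it goes: the month's excursion frequency (fETE) times the
retained (longest) excursion distance of a given night. It is dimensioned
in metres and gives one record per excursion night; a month-level value is
the mean of that badger's nightly records within the month.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEASON_HIGH = "high"   # April-September: higher badger activity
SEASON_LOW = "low"     # October-March: lower activity, winter lethargy

MONTHLY_KEY = ["animal_id", "year", "month"]


def season_label(month: int) -> str:
    """Map a calendar month to the high (Apr-Sep) / low (Oct-Mar) activity season."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be 1-12, got {month}")
    return SEASON_HIGH if 4 <= int(month) <= 9 else SEASON_LOW


def investment(monthly: pd.DataFrame, etes: pd.DataFrame) -> pd.DataFrame:
    """One record per ETE night: month fETE x that night's retained distance.

    Months with fETE = 0 have no excursion nights, hence no records.
    """
    if etes.empty:
        return pd.DataFrame(columns=MONTHLY_KEY + [
            "night_date", "fete_of_month", "max_distance_that_night_m", "investment"])
    fete = monthly[MONTHLY_KEY + ["fete"]].rename(columns={"fete": "fete_of_month"})
    rec = etes[MONTHLY_KEY + ["night_date", "distance_m"]].rename(
        columns={"distance_m": "max_distance_that_night_m"})
    rec = rec.merge(fete, on=MONTHLY_KEY, how="left")
    if rec["fete_of_month"].isna().any():
        raise ValueError("ETE events without a matching monthly assessment record")
    rec["investment"] = rec["fete_of_month"] * rec["max_distance_that_night_m"]
    return rec


def monthly_investment(invest: pd.DataFrame) -> pd.DataFrame:
    """Month-level investment: mean of a badger's nightly records that month."""
    if invest.empty:
        return pd.DataFrame(columns=MONTHLY_KEY + ["investment"])
    return invest.groupby(MONTHLY_KEY, as_index=False)["investment"].mean()


def _box_stats(values: pd.Series) -> dict:
    """Boxplot-style summary: quartiles (linear interpolation) and 1.5xIQR whiskers."""
    v = values.dropna().to_numpy(dtype=float)
    if len(v) == 0:
        return {"n": 0, "mean": np.nan, "median": np.nan, "q1": np.nan,
                "q3": np.nan, "whisker_low": np.nan, "whisker_high": np.nan}
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if len(inside) else np.nan,
        "whisker_high": float(inside.max()) if len(inside) else np.nan,
    }


def cohort_summaries(
    monthly: pd.DataFrame,
    group_by: list[str],
    value: str = "fete",
) -> pd.DataFrame:
    """Boxplot statistics of ``value`` per cohort defined by ``group_by``.

    ``group_by`` may mix the metadata columns (sex, month, age_cohort,
    breeding_status) with the derived 'season' key. Also reports the
    proportion of badgers in each cohort that made at least one ETE, the
    quantity behind the monthly male/female participation comparison.
    """
    df = monthly.copy()
    if "season" in group_by and "season" not in df.columns:
        df["season"] = df["month"].map(season_label)
    for key in group_by:
        if key not in df.columns:
            raise KeyError(f"grouping column {key!r} not present")
    rows = []
    for keys, grp in df.groupby(group_by, sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        stats = _box_stats(grp[value])
        if "ete_count" in grp.columns and len(grp):
            stats["proportion_with_ete"] = float((grp["ete_count"] > 0).mean())
        else:
            stats["proportion_with_ete"] = np.nan
        rows.append(dict(zip(group_by, keys)) | stats)
    return pd.DataFrame(rows)
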