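#!/usr/bin/env python
"""Cohort summaries and the excursion 'investment' metric.

Summarises excursion frequency and distance by sex, month, age cohort and
season (boxplot statistics plus the proportion of badgers making any
excursion), and computes the nightly investment records — month fETE times
the night's retained excursion distance.
"""

from pathlib import Path

import pandas as pd

from foray.io import write_table
from foray.metrics import cohort_summaries, investment, monthly_investment

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = ROOT / "results"
    monthly = pd.read_csv(res / "monthly_assessments.csv")
    etes = pd.read_csv(res / "ete_events.csv")

    invest = investment(monthly, etes)
    write_table(invest, res / "investment.csv")
    write_table(monthly_investment(invest), res / "investment_monthly.csv")

    for name, keys, value in [
        ("fete_by_sex_month", ["sex", "month"], "fete"),
        ("fete_by_age_cohort", ["age_cohort"], "fete"),
        ("fete_by_season_sex", ["season", "sex"], "fete"),
    ]:
        write_table(cohort_summaries(monthly, keys, value), res / f"summary_{name}.csv")
    dist = cohort_summaries(
        etes.merge(monthly[["animal_id", "year", "month", "sex", "age_cohort"]],
                   on=["animal_id", "year", "month"]).assign(ete_count=1),
        ["sex", "month"], value="distance_m")
    write_table(dist, res / "summary_distance_by_sex_month.csv")

    season = cohort_summaries(monthly, ["season"], "fete")
    print("fETE by season (median):")
    for row in season.itertuples(index=False):
        print(f"  {row.season}: median {row.median:.3f}, mean {row.mean:.3f}, "
              f"n {row.n}, proportion with an excursion {row.proportion_with_ete:.2f}")
    print(f"{len(invest)} nightly investment records "
          f"(median {invest['investment'].median():.1f} m)")


if __name__ == "__main__":
    main()
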