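#!/usr/bin/env python
"""Comparison statistics and the excursion-frequency GLMM.

Runs the seasonal Wilcoxon signed-rank comparison of the monthly
proportions of males vs females making excursions, the Pearson correlation
between monthly excursion frequency and nightly excursion distance, and
fits the zero-inflated binomial mixed model for fETE (age cohort + month +
sex, with year and animal-in-group random intercepts). --dredge also ranks
every marginality-respecting fixed-effect subset by AICc.
"""

import argparse
from pathlib import Path

import pandas as pd

from foray.io import write_table
from foray.mixedmodels import ModelSpec, fit_model, model_selection_aicc, pairwise_contrasts
from foray.pipeline import _sex_proportion_pairs
from foray.stats import pearson_test, wilcoxon_signed_rank

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dredge", action="store_true",
                    help="rank all AICc subsets (slower)")
    ap.add_argument("--month-coding", choices=["categorical", "linear"],
                    default="categorical")
    args = ap.parse_args()

    res = ROOT / "results"
    monthly = pd.read_csv(res / "monthly_assessments.csv")
    etes = pd.read_csv(res / "ete_events.csv")

    rows = []
    for season, months in [("high (Apr-Sep)", tuple(range(4, 10))),
                           ("low (Oct-Mar)", (10, 11, 12, 1, 2, 3))]:
        pairs = _sex_proportion_pairs(monthly, months)
        t = wilcoxon_signed_rank(pairs)
        rows.append({"test": f"wilcoxon sex proportions, {season}",
                     "statistic": t.statistic_W, "p": t.p_value, "n": t.n_pairs})
        print(f"male vs female monthly excursion proportions, {season}: "
              f"W = {t.statistic_W:.1f}, p = {t.p_value:.3f} ({t.n_pairs} month-pairs)")

    joined = etes.merge(monthly[["animal_id", "year", "month", "fete"]],
                        on=["animal_id", "year", "month"])
    c = pearson_test(joined["fete"], joined["distance_m"])
    rows.append({"test": "pearson fETE vs nightly distance",
                 "statistic": c.t_statistic, "p": c.p_value, "n": c.df + 2})
    print(f"fETE vs excursion distance: r = {c.r:.3f}, t = {c.t_statistic:.2f}, "
          f"df = {c.df}, p = {c.p_value:.2g}")
    write_table(pd.DataFrame(rows), res / "comparison_tests.csv")

    spec = ModelSpec(response="fete", fixed_effects=("age_cohort", "month", "sex"),
                     month_coding=args.month_coding)
    if args.dredge:
        table, fit = model_selection_aicc(monthly, spec)
        write_table(table, res / "aicc_ranking.csv")
        print(f"best AICc model: {table.iloc[0]['fixed_effects']} "
              f"(AICc {table.iloc[0]['aicc']:.1f})")
    else:
        fit = fit_model(monthly, spec)
    out = fit.coefficients.assign(component="conditional")
    if fit.zi_coefficients is not None:
        out = pd.concat([out, fit.zi_coefficients.assign(component="zero_inflation")])
    write_table(out, res / "model_results.csv")
    print(f"fETE GLMM (converged={fit.converged}, AICc {fit.aicc:.1f}):")
    print(fit.coefficients.to_string(index=False))
    print("age-cohort contrasts (Holm-adjusted):")
    print(pairwise_contrasts(fit, "age_cohort").to_string(index=False))


if __name__ == "__main__":
    main()
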