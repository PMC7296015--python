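"""GLMM contract: effect recovery, AICc selection, contrasts.

These tests run the glmmTMB estimation engine on simulated regression data
with known effects and all random-effect variances genuinely positive (a
variance collapsing to the boundary makes Wald standard errors undefined).
"""

import numpy as np
import pandas as pd
import pytest

from foray.mixedmodels import (
    ModelSpec,
    enumerate_subsets,
    fit_model,
    fit_models,
    fit_replicates,
    model_selection_aicc,
    pairwise_contrasts,
)

COHORTS = ("Juvenile", "YoungAdult", "OlderAdult")


def make_fete_data(rng, n_animals=48, n_months=12, sex_effect=0.5,
                   zi_prob=0.25, nights=30, replicate=None):
    """Zero-inflated binomial badger-months with year/group/animal intercepts."""
    n_groups = max(n_animals // 5, 2)
    u_animal = rng.normal(0, 0.3, n_animals)
    u_year = rng.normal(0, 0.2, 4)
    u_group = rng.normal(0, 0.2, n_groups)
    rows = []
    for a in range(n_animals):
        g = min(a // (n_animals // n_groups), n_groups - 1)  # sexes alternate within groups
        sex = "M" if a % 2 else "F"
        for m in range(1, n_months + 1):
            yr = 2010 + (a + m) % 4
            eta = -2.0 + sex_effect * (sex == "M") + u_animal[a] + u_year[yr - 2010] + u_group[g]
            k = rng.binomial(nights, 1 / (1 + np.exp(-eta)))
            if rng.random() < zi_prob:
                k = 0
            rows.append(dict(animal_id=f"A{a}", group_id=f"G{g}", year=yr, month=m,
                             ete_count=k, active_nights=nights, sex=sex,
                             age_cohort=COHORTS[a % 3]))
    df = pd.DataFrame(rows)
    if replicate is not None:
        df["replicate"] = replicate
    return df


def make_distance_data(rng, n_events=2000, sex_effect=0.5):
    """Log-normal excursion distances with a male-female shift on the log scale."""
    n_animals, n_groups = 60, 10
    u_animal = rng.normal(0, 0.25, n_animals)
    u_year = rng.normal(0, 0.15, 4)
    u_group = rng.normal(0, 0.15, n_groups)
    a_idx = rng.integers(0, n_animals, n_events)
    months = rng.integers(1, 13, n_events)
    years = rng.integers(0, 4, n_events)
    sex_m = a_idx % 2 == 1
    g_idx = a_idx // (n_animals // n_groups)  # sexes alternate within groups
    mu = (np.log(120.0) + sex_effect * sex_m
          + u_animal[a_idx] + u_year[years] + u_group[g_idx])
    return pd.DataFrame({
        "animal_id": [f"A{i}" for i in a_idx],
        "group_id": [f"G{i}" for i in g_idx],
        "year": 2010 + years, "month": months,
        "sex": np.where(sex_m, "M", "F"),
        "age_cohort": [COHORTS[i % 3] for i in a_idx],
        "distance_m": np.exp(mu + rng.normal(0, 0.5, n_events)),
    })


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(response="fete", fixed_effects=("month:sex",))

    def test_unknown_terms_rejected(self):
        with pytest.raises(ValueError, match="unknown fixed effects"):
            ModelSpec(response="fete", fixed_effects=("weight",))

    def test_lattice_counts(self):
        small = ModelSpec(response="fete", fixed_effects=("sex", "month", "month:sex"))
        assert len(enumerate_subsets(small)) == 5
        full = ModelSpec(response="fete", fixed_effects=(
            "age_cohort", "month", "sex", "age_cohort:month", "month:sex"))
        assert len(enumerate_subsets(full)) == 13
        for spec in enumerate_subsets(full):
            for term in spec.fixed_effects:
                if ":" in term:
                    assert all(m in spec.fixed_effects for m in term.split(":"))

    def test_month_coding_switch(self):
        cat = ModelSpec(response="fete", fixed_effects=("month",))
        lin = ModelSpec(response="fete", fixed_effects=("month",), month_coding="linear")
        assert cat.formula_rhs() == "month_f"
        assert lin.formula_rhs() == "month_num"

    def test_log_response_requires_positive_values(self):
        df = make_distance_data(np.random.default_rng(0), n_events=50)
        df.loc[0, "distance_m"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_model(df, ModelSpec(response="log_distance", fixed_effects=("sex",)))


@pytest.fixture(scope="module")
def fete_fits():
    """One batched R session: intercept-only and age+sex models on the same data."""
    df = make_fete_data(np.random.default_rng(7), sex_effect=0.8)
    specs = [ModelSpec(response="fete"),
             ModelSpec(response="fete", fixed_effects=("age_cohort", "sex"))]
    null_fit, sex_fit = fit_models(df, specs)
    return df, null_fit, sex_fit


class TestFeteModel:
    def test_sex_effect_recovered(self, fete_fits):
        _, _, fit = fete_fits
        assert fit.converged
        sex = fit.coefficients.set_index("term").loc["sexM"]
        assert sex["estimate"] == pytest.approx(0.8, abs=3 * sex["std_error"])

    def test_structural_zero_estimated(self, fete_fits):
        _, _, fit = fete_fits
        assert 0.15 < fit.structural_zero_probability < 0.35  # designed 0.25

    def test_strong_effect_beats_intercept_on_aicc(self, fete_fits):
        _, null_fit, sex_fit = fete_fits
        assert sex_fit.aicc < null_fit.aicc

    def test_pairwise_contrasts_count_and_adjustment(self, fete_fits):
        _, _, fit = fete_fits
        table = pairwise_contrasts(fit, "age_cohort")
        assert len(table) == 3  # 3-level factor -> 3 contrasts
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
        with pytest.raises(KeyError):
            pairwise_contrasts(fit, "breeding_status")


class TestGaussianModel:
    def test_log_distance_effect_recovery(self):
        df = make_distance_data(np.random.default_rng(11), n_events=2000, sex_effect=0.5)
        fit = fit_model(df, ModelSpec(response="log_distance", fixed_effects=("sex",)))
        assert fit.converged
        est = fit.coefficients.set_index("term").loc["sexM", "estimate"]
        assert est == pytest.approx(0.5, abs=0.15)


class TestTypeICoverage:
    def test_null_sex_effect_ci_covers_zero(self):
        # 50 independent replicates with no sex effect: the 95% Wald CI for
        # the sex coefficient must cover zero in at least 90% of them
        rng = np.random.default_rng(2024)
        stacks = [make_fete_data(rng, n_animals=24, n_months=10,
                                 sex_effect=0.0, replicate=i)
                  for i in range(50)]
        df = pd.concat(stacks, ignore_index=True)
        fits = fit_replicates(df, ModelSpec(response="fete", fixed_effects=("sex",)))
        covered = 0
        usable = 0
        for f in fits:
            if not f.converged:
                continue
            row = f.coefficients.set_index("term").loc["sexM"]
            if not np.isfinite(row["std_error"]):
                continue
            usable += 1
            lo = row["estimate"] - 1.96 * row["std_error"]
            hi = row["estimate"] + 1.96 * row["std_error"]
            covered += lo <= 0 <= hi
        assert usable >= 40
        assert covered / usable >= 0.90


@pytest.fixture(scope="module")
def interaction_data():
    # strong linear month-by-sex interaction on the log-distance response:
    # males lengthen their excursions over the year, females do not
    rng = np.random.default_rng(5)
    df = make_distance_data(rng, n_events=1500, sex_effect=0.0)
    male = (df["sex"] == "M").to_numpy()
    df["distance_m"] *= np.exp(0.15 * (df["month"].to_numpy() - 6.5) * male)
    return df


class TestModelSelection:
    def test_saturated_best_under_strong_interaction(self, interaction_data):
        spec = ModelSpec(response="log_distance",
                         fixed_effects=("sex", "month", "month:sex"),
                         month_coding="linear")
        table, best = model_selection_aicc(interaction_data, spec)
        assert len(table) == 5
        assert set(best.spec.fixed_effects) == {"sex", "month", "month:sex"}
        assert table["delta_aicc"].min() == pytest.approx(0.0)

    def test_null_competitive_without_effects(self):
        rng = np.random.default_rng(8)
        df = make_distance_data(rng, n_events=400, sex_effect=0.0)
        spec = ModelSpec(response="log_distance", fixed_effects=("sex",))
        table, best = model_selection_aicc(df, spec)
        null_row = table[table["fixed_effects"] == "(intercept only)"].iloc[0]
        assert null_row["delta_aicc"] <= 4.0
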