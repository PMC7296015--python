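"""Mixed-effects models for excursion frequency, distance and investment.

Monthly excursion frequency is modelled as a zero-inflated binomial GLMM:
the count part is ete_count successes out of active_nights trials on a
logit link, the structural-zero part is an intercept-only logistic
component (a latent class of badger-months that never excurse, beyond what
the binomial predicts), and random intercepts are year plus animal nested
in social group — the structure that guards against pseudoreplication when
the same badgers contribute many months. Log distance and log investment
use the same random-effects structure with a Gaussian response.

Estimation is delegated to glmmTMB (R), the standard engine for
zero-inflated GLMMs, through a batch Rscript bridge; model enumeration,
AICc ranking and post-hoc contrasts are computed here.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import aicc, holm_adjust

RESPONSES = ("fete", "log_distance", "log_investment")
FIXED_EFFECT_TERMS = ("age_cohort", "month", "sex", "age_cohort:month", "month:sex")
RANDOM_EFFECTS = "(1|year) + (1|group_id/animal_id)"


class ModelFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects subset over the fixed year/animal-in-group random structure."""

    response: str
    fixed_effects: tuple[str, ...] = ()
    month_coding: str = "categorical"  # categorical (11 df) | linear (1 df)

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.month_coding not in ("categorical", "linear"):
            raise ValueError("month_coding must be 'categorical' or 'linear'")
        unknown = set(self.fixed_effects) - set(FIXED_EFFECT_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed effects {sorted(unknown)}")
        for term in self.fixed_effects:
            if ":" in term:
                for main in term.split(":"):
                    if main not in self.fixed_effects:
                        raise ValueError(
                            f"interaction {term} requires main effect {main} (marginality)"
                        )

    @property
    def family(self) -> str:
        return "zibinomial" if self.response == "fete" else "gaussian"

    def formula_rhs(self) -> str:
        if not self.fixed_effects:
            return "1"
        month_col = "month_f" if self.month_coding == "categorical" else "month_num"
        return " + ".join(t.replace("month", month_col) for t in self.fixed_effects)


@dataclass
class ModelFit:
    spec: ModelSpec
    converged: bool
    loglik: float
    k: int                      # estimated parameters (from logLik df)
    n: int
    aic: float
    aicc: float
    coefficients: pd.DataFrame  # term, estimate, std_error, z, p_value
    zi_coefficients: pd.DataFrame | None = None
    vcov: pd.DataFrame | None = None
    error: str | None = None
    factor_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def structural_zero_probability(self) -> float:
        """Estimated structural-zero fraction, inverse-logit of the zi intercept."""
        if self.zi_coefficients is None or self.zi_coefficients.empty:
            raise ModelFitError("model has no zero-inflation component")
        eta = float(self.zi_coefficients["estimate"].iloc[0])
        return float(1 / (1 + np.exp(-eta)))


def _rscript() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise ModelFitError("Rscript not found on PATH; glmmTMB engine unavailable")
    return exe


def prepare_model_data(data: pd.DataFrame, response: str) -> pd.DataFrame:
    """Select and validate the columns one response type needs."""
    df = data.copy()
    required = {"year", "group_id", "animal_id", "month"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"model data missing columns {sorted(missing)}")
    df["month_f"] = "m" + df["month"].astype(int).astype(str).str.zfill(2)
    df["month_num"] = df["month"].astype(int)
    if response == "fete":
        if not {"ete_count", "active_nights"}.issubset(df.columns):
            raise ValueError("fete models need ete_count and active_nights columns")
    else:
        src = "distance_m" if response == "log_distance" else "investment"
        if "y" not in df.columns:
            if src not in df.columns:
                raise ValueError(f"{response} models need a '{src}' (or 'y') column")
            vals = df[src].astype(float)
            if (vals <= 0).any():
                raise ValueError(f"{src} must be positive for log transformation")
            df["y"] = np.log(vals)
    return df


def _run_bridge(df: pd.DataFrame, models: list[dict]) -> list[dict]:
    script = resources.files("foray").joinpath("r/fit_glmmtmb.R")
    factors = [c for c in ("year", "group_id", "animal_id", "sex", "age_cohort", "month_f")
               if c in df.columns]
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_csv = tmp / "data.csv"
        df.to_csv(data_csv, index=False)
        job = {
            "data_csv": str(data_csv),
            "models": models,
            "random": RANDOM_EFFECTS,
            "factors": factors,
        }
        job_path = tmp / "job.json"
        out_path = tmp / "out.json"
        job_path.write_text(json.dumps(job))
        with resources.as_file(script) as script_path:
            proc = subprocess.run(
                [_rscript(), str(script_path), str(job_path), str(out_path)],
                capture_output=True, text=True,
            )
        if proc.returncode != 0 or not out_path.exists():
            raise ModelFitError(f"glmmTMB bridge failed:\n{proc.stderr[-2000:]}")
        return json.loads(out_path.read_text())


def _coef_frame(block: dict | None) -> pd.DataFrame:
    cols = ["term", "estimate", "std_error", "z", "p_value"]
    if not block:
        return pd.DataFrame(columns=cols)
    # jsonlite unboxes length-1 vectors to scalars
    block = {c: v if isinstance(v, list) else [v] for c, v in block.items()}
    df = pd.DataFrame({c: block[c] for c in cols})
    for c in cols[1:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def _result_to_fit(spec: ModelSpec, res: dict, df: pd.DataFrame) -> ModelFit:
    if "error" in res and res.get("loglik") is None and res.get("coefficients") is None:
        return ModelFit(spec=spec, converged=False, loglik=np.nan, k=0,
                        n=len(df), aic=np.nan, aicc=np.nan,
                        coefficients=_coef_frame(None), error=res.get("error"))
    # a boundary fit can report NA logLik/AIC while still carrying estimates;
    # surface what exists and flag non-convergence
    loglik = float(res["loglik"]) if res.get("loglik") is not None else np.nan
    k = int(res["df"]) if res.get("df") is not None else 0
    n = int(res["nobs"]) if res.get("nobs") is not None else len(df)
    vcov = None
    if res.get("vcov") is not None:
        terms = res["vcov_terms"]
        if not isinstance(terms, list):
            terms = [terms]
        mat = np.atleast_2d(np.array(res["vcov"], dtype=float))
        vcov = pd.DataFrame(mat, index=terms, columns=terms)
    levels = {
        c: sorted(df[c].astype(str).unique())
        for c in ("sex", "age_cohort", "month_f") if c in df.columns
    }
    return ModelFit(
        spec=spec,
        converged=bool(res.get("converged", False)),
        loglik=loglik, k=k, n=n,
        aic=float(res["aic"]) if res.get("aic") is not None else np.nan,
        aicc=aicc(loglik, k, n) if np.isfinite(loglik) else np.nan,
        coefficients=_coef_frame(res.get("coefficients")),
        zi_coefficients=_coef_frame(res.get("zi_coefficients")) if res.get("zi_coefficients") else None,
        vcov=vcov,
        error=res.get("error"),
        factor_levels=levels,
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one GLMM; non-convergence is flagged on the result, never silent."""
    df = prepare_model_data(data, spec.response)
    res = _run_bridge(df, [{"id": "m0", "family": spec.family, "fixed": spec.formula_rhs()}])
    return _result_to_fit(spec, res[0], df)


def fit_models(data: pd.DataFrame, specs: list[ModelSpec]) -> list[ModelFit]:
    """Fit several specs of the same response in one R session (batch)."""
    responses = {s.response for s in specs}
    if len(responses) != 1:
        raise ValueError("batch fits must share a response")
    df = prepare_model_data(data, specs[0].response)
    models = [{"id": f"m{i}", "family": s.family, "fixed": s.formula_rhs()}
              for i, s in enumerate(specs)]
    results = {r["id"]: r for r in _run_bridge(df, models)}
    return [_result_to_fit(s, results[f"m{i}"], df) for i, s in enumerate(specs)]


def fit_replicates(data: pd.DataFrame, spec: ModelSpec,
                   replicate_col: str = "replicate") -> list[ModelFit]:
    """Fit the same spec independently on each replicate subset, in one R session.

    ``data`` is a stack of replicate datasets distinguished by
    ``replicate_col``; useful for simulation studies (coverage, power).
    """
    df = prepare_model_data(data, spec.response)
    if replicate_col != "replicate":
        df = df.rename(columns={replicate_col: "replicate"})
    if "replicate" not in df.columns:
        raise ValueError(f"missing replicate column {replicate_col!r}")
    reps = sorted(df["replicate"].unique().tolist())
    models = [{"id": f"r{i}", "family": spec.family, "fixed": spec.formula_rhs(),
               "subset": rep} for i, rep in enumerate(reps)]
    results = {r["id"]: r for r in _run_bridge(df, models)}
    return [_result_to_fit(spec, results[f"r{i}"], df[df["replicate"] == rep])
            for i, rep in enumerate(reps)]


def enumerate_subsets(saturated: ModelSpec) -> list[ModelSpec]:
    """All fixed-effect subsets of the saturated spec that respect marginality."""
    mains = [t for t in saturated.fixed_effects if ":" not in t]
    inters = [t for t in saturated.fixed_effects if ":" in t]
    specs = []
    for r in range(len(mains) + 1):
        for main_subset in combinations(mains, r):
            allowed = [i for i in inters if all(m in main_subset for m in i.split(":"))]
            for ri in range(len(allowed) + 1):
                for int_subset in combinations(allowed, ri):
                    fixed = tuple(
                        t for t in saturated.fixed_effects
                        if t in main_subset or t in int_subset
                    )
                    specs.append(replace(saturated, fixed_effects=fixed))
    return specs


def model_selection_aicc(data: pd.DataFrame, saturated: ModelSpec) -> tuple[pd.DataFrame, ModelFit]:
    """Fit every marginality-respecting subset and rank by AICc.

    Returns the ranking table (ascending AICc, non-convergent fits flagged
    and excluded from 'best') and the best converged fit.
    """
    specs = enumerate_subsets(saturated)
    fits = fit_models(data, specs)
    rows = []
    for spec, f in zip(specs, fits):
        rows.append({
            "fixed_effects": " + ".join(spec.fixed_effects) or "(intercept only)",
            "k": f.k, "loglik": f.loglik, "aicc": f.aicc,
            "converged": f.converged,
        })
    table = pd.DataFrame(rows)
    ok = table["converged"] & np.isfinite(table["aicc"])
    if not ok.any():
        raise ModelFitError("no model in the lattice converged")
    best_aicc = table.loc[ok, "aicc"].min()
    table["delta_aicc"] = table["aicc"] - best_aicc
    table = table.sort_values(["converged", "aicc"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    best_idx = int(np.argmin([f.aicc if f.converged and np.isfinite(f.aicc) else np.inf
                              for f in fits]))
    return table, fits[best_idx]


def pairwise_contrasts(fit: ModelFit, factor: str) -> pd.DataFrame:
    """All pairwise level contrasts of a main-effect factor, Holm-adjusted.

    Works on the treatment-coded main-effect coefficients of the
    conditional model (contrasts are at the reference levels of any other
    factors when interactions are present).
    """
    col = "month_f" if factor == "month" and "month_f" in fit.factor_levels else factor
    levels = fit.factor_levels.get(col)
    if not levels:
        raise KeyError(f"factor {factor!r} not in the fitted model's data")
    if fit.vcov is None:
        raise ModelFitError("fit has no coefficient covariance (non-convergence?)")
    coef = fit.coefficients.set_index("term")["estimate"]
    name = {lev: f"{col}{lev}" for lev in levels}
    present = [lev for lev in levels if lev == levels[0] or name[lev] in coef.index]
    if len(present) < 2:
        raise KeyError(f"factor {factor!r} has no estimated coefficients in this model")

    def beta(lev: str) -> float:
        return 0.0 if lev == present[0] else float(coef[name[lev]])

    def cov(l1: str, l2: str) -> float:
        if l1 == present[0] or l2 == present[0]:
            return 0.0
        return float(fit.vcov.loc[name[l1], name[l2]])

    rows = []
    for a, b in combinations(present, 2):
        est = beta(a) - beta(b)
        var = cov(a, a) + cov(b, b) - 2 * cov(a, b)
        se = np.sqrt(var) if var > 0 else np.nan
        z = est / se if se and np.isfinite(se) else np.nan
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "std_error": se,
                     "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_adjust(out["p_value"].fillna(1.0).to_numpy())
    return out
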