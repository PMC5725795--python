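"""Regression battery fitted on each simulated cohort.

The study compares how the estimated exposure (ICS) coefficient behaves
across outcome parametrizations:

* ``M1``  — BW ~ ICS                     (OLS; total effect)
* ``M2``  — BW ~ ICS + GA                (OLS; direct effect)
* ``M2*`` — BW ~ ICS + GA + GA^2 + GA^3  (OLS; direct effect, cubic variant)
* ``M3``  — LBW ~ ICS                    (logistic; total effect)
* ``M4``  — SGA ~ ICS                    (logistic; direct effect)

plus V-adjusted versions (``M1,V`` ... ``M4,V``) in the confounding
scenarios. Only the ICS coefficient is extracted: a mean difference in grams
for the linear models, a log odds ratio for the logistic ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .scenarios import ScenarioSpec, Variant

__all__ = ["ModelSpec", "FitResult", "MODEL_SPECS", "fit_model", "fit_linear", "fit_logistic", "model_battery"]

#: Canonical row order within a scenario, matching the published tables.
MODEL_ORDER = ("M1", "M1,V", "M2", "M2,V", "M2*", "M2,V*", "M3", "M3,V", "M4", "M4,V")

LOGIT_TOL = 1e-8
LOGIT_MAXITER = 100


@dataclass(frozen=True)
class ModelSpec:
    """One regression model: outcome, family, and covariate set."""

    name: str
    outcome: str  # bw | lbw | sga
    family: str  # linear | logistic
    covariates: tuple[str, ...]  # columns/terms beyond the intercept; ics first

    def __post_init__(self) -> None:
        if "ics" not in self.covariates:
            raise ValueError("ICS must always be a covariate")
        if (self.outcome == "bw") != (self.family == "linear"):
            raise ValueError("BW pairs with the linear family; LBW/SGA with logistic")


def _ms(name, outcome, family, covs):
    return ModelSpec(name, outcome, family, tuple(covs))


MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": _ms("M1", "bw", "linear", ["ics"]),
    "M1,V": _ms("M1,V", "bw", "linear", ["ics", "v"]),
    "M2": _ms("M2", "bw", "linear", ["ics", "ga"]),
    "M2,V": _ms("M2,V", "bw", "linear", ["ics", "ga", "v"]),
    "M2*": _ms("M2*", "bw", "linear", ["ics", "ga", "ga2", "ga3"]),
    "M2,V*": _ms("M2,V*", "bw", "linear", ["ics", "ga", "ga2", "ga3", "v"]),
    "M3": _ms("M3", "lbw", "logistic", ["ics"]),
    "M3,V": _ms("M3,V", "lbw", "logistic", ["ics", "v"]),
    "M4": _ms("M4", "sga", "logistic", ["ics"]),
    "M4,V": _ms("M4,V", "sga", "logistic", ["ics", "v"]),
}


@dataclass(frozen=True)
class FitResult:
    """Estimated ICS coefficient from one model on one cohort."""

    model: str
    beta_ics: float
    converged: bool


def _design_matrix(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for name in covariates:
        if name in ("ga2", "ga3"):
            power = int(name[-1])
            cols.append(cohort["ga"].to_numpy(dtype=float) ** power)
        else:
            cols.append(cohort[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_linear(cohort: pd.DataFrame, covariates, name: str = "linear") -> FitResult:
    """OLS fit of BW on the covariates; returns the ICS coefficient.

    Raises on a rank-deficient design (e.g. a constant exposure column):
    the ICS coefficient would not be identified.
    """
    covariates = tuple(covariates)
    X = _design_matrix(cohort, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{name}: design matrix is rank deficient")
    res = sm.OLS(cohort["bw"].to_numpy(dtype=float), X).fit()
    beta = float(res.params[1 + covariates.index("ics")])
    return FitResult(model=name, beta_ics=beta, converged=True)


def fit_logistic(cohort: pd.DataFrame, covariates, outcome: str, name: str = "logistic") -> FitResult:
    """Maximum-likelihood logistic fit; returns the ICS log odds ratio.

    A degenerate outcome (a single class) raises; separation or
    non-convergence is surfaced via ``converged=False``, never clamped.
    """
    covariates = tuple(covariates)
    y = cohort[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"{name}: outcome {outcome!r} has a single class")
    X = _design_matrix(cohort, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{name}: design matrix is rank deficient")
    try:
        res = sm.Logit(y, X).fit(
            method="newton", tol=LOGIT_TOL, maxiter=LOGIT_MAXITER, disp=False
        )
        converged = bool(res.mle_retvals.get("converged", False))
        beta = float(res.params[1 + covariates.index("ics")])
    except (np.linalg.LinAlgError, PerfectSeparationError):
        converged, beta = False, float("nan")
    if not np.isfinite(beta):
        converged = False
    return FitResult(model=name, beta_ics=beta, converged=converged)


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    if spec.family == "linear":
        return fit_linear(cohort, spec.covariates, name=spec.name)
    return fit_logistic(cohort, spec.covariates, spec.outcome, name=spec.name)


def model_battery(scenario: ScenarioSpec, variant: Variant | None = None) -> list[ModelSpec]:
    """The models fitted under a scenario/variant, in table order.

    Basic scenarios: M1, M2, M3, M4 (plus M2* under the cubic-mean variant).
    Confounding scenarios: additionally the V-adjusted version of each
    (plus M2,V* under the cubic-mean variant).
    """
    variant = variant or Variant()
    names = ["M1", "M2", "M3", "M4"]
    if variant.mean_form == "cubic":
        names.insert(2, "M2*")
    if scenario.has_confounder:
        expanded = []
        for name in names:
            expanded.append(name)
            expanded.append("M2,V*" if name == "M2*" else f"{name},V")
        names = expanded
    return [MODEL_SPECS[name] for name in names]
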