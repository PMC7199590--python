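"""Base and enhanced logistic mortality models with Wald odds-ratio tables.

The base model predicts mortality (ICU, in-hospital, or 90-day) from age,
sex, comorbidity-count category (dummy-coded against 0 conditions), SOFA
score, and PaO2/FiO2; the enhanced model adds the baseline RDW. Fitting is
maximum likelihood by iteratively reweighted least squares; odds ratios are
exp(coefficient) with 95% Wald intervals. No regularisation: complete
separation surfaces as non-convergence and is reported, never penalised
away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_data import CohortTable
from .errors import (
    CollinearityError,
    DegenerateOutcomeError,
    NotConvergedError,
    SchemaError,
)

OUTCOMES = {"icu": "icu_death", "hospital": "hosp_death", "day90": "death_90d"}

BASE_COVARIATES = (
    "age",
    "male",
    "comorbid_1",
    "comorbid_2",
    "comorbid_3plus",
    "sofa",
    "pf_ratio",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome to model and whether baseline RDW enters the design."""

    outcome: str = "icu"
    include_rdw: bool = False
    covariates: tuple[str, ...] = BASE_COVARIATES

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise SchemaError(
                f"outcome must be one of {sorted(OUTCOMES)}, got {self.outcome!r}"
            )

    @property
    def design_columns(self) -> tuple[str, ...]:
        cols = ("const",) + tuple(self.covariates)
        if self.include_rdw:
            cols += ("rdw_baseline",)
        return cols


@dataclass(frozen=True)
class FittedLogisticModel:
    """Coefficients, covariance, and convergence state for one outcome model."""

    spec: ModelSpec
    coefficients: pd.Series
    covariance: pd.DataFrame
    converged: bool
    n_used: int
    deviance: float


def design_matrix(cohort: CohortTable, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the (X, y) pair for a model spec from a validated cohort.

    Sex enters as a male indicator; the comorbidity category is dummy-coded
    with "0 conditions" as the reference.
    """
    frame = cohort.to_frame()
    X = pd.DataFrame(
        {
            "const": 1.0,
            "age": frame["age"].astype(float),
            "male": (frame["sex"] == "male").astype(float),
            "comorbid_1": (frame["comorbidity_category"] == "1").astype(float),
            "comorbid_2": (frame["comorbidity_category"] == "2").astype(float),
            "comorbid_3plus": (frame["comorbidity_category"] == "3plus").astype(float),
            "sofa": frame["sofa"].astype(float),
            "pf_ratio": frame["pf_ratio"].astype(float),
            "rdw_baseline": frame["rdw_baseline"].astype(float),
        }
    )
    X = X[list(spec.design_columns)]
    y = frame[OUTCOMES[spec.outcome]].to_numpy(dtype=float)
    return X, y


def fit_logistic(cohort: CohortTable, spec: ModelSpec) -> FittedLogisticModel:
    """Fit one logistic model by IRLS (deviance tolerance 1e-8, 50 iterations).

    Raises if the outcome is constant or the design is rank deficient; a fit
    that hits the iteration cap is returned with ``converged=False`` and the
    caller decides what to do with it.
    """
    if len(cohort) == 0:
        raise DegenerateOutcomeError("empty cohort")
    X, y = design_matrix(cohort, spec)
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            f"outcome {spec.outcome!r} is constant ({int(y[0])} for every patient)"
        )
    _check_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=50, tol=1e-8, tol_criterion="deviance")
    return FittedLogisticModel(
        spec=spec,
        coefficients=res.params.copy(),
        covariance=pd.DataFrame(
            np.asarray(res.cov_params()), index=X.columns, columns=X.columns
        ),
        converged=bool(res.converged),
        n_used=len(y),
        deviance=float(res.deviance),
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    # scale columns so rank detection is unit-free
    norms = np.linalg.norm(arr, axis=0)
    norms[norms == 0] = 1.0
    r = np.linalg.qr(arr / norms, mode="r")
    small = np.abs(np.diag(r)) < 1e-8
    if small.any():
        cols = tuple(X.columns[i] for i in np.flatnonzero(small))
        raise CollinearityError(
            f"design matrix rank deficient; collinear column(s): {cols}", columns=cols
        )


def odds_ratios(model: FittedLogisticModel) -> pd.DataFrame:
    """Odds ratios with 95% Wald intervals, one row per non-intercept term."""
    if not model.converged:
        raise NotConvergedError(
            "refusing to report odds ratios from a non-converged fit"
        )
    terms = [t for t in model.coefficients.index if t != "const"]
    coefs = model.coefficients[terms]
    se = np.sqrt(np.diag(model.covariance.loc[terms, terms]))
    return pd.DataFrame(
        {
            "term": terms,
            "or": np.exp(coefs.to_numpy()),
            "ci_low": np.exp(coefs.to_numpy() - 1.96 * se),
            "ci_high": np.exp(coefs.to_numpy() + 1.96 * se),
        }
    ).set_index("term")


def predict_probability(model: FittedLogisticModel, cohort: CohortTable) -> np.ndarray:
    """Per-patient predicted event probability, strictly inside (0, 1)."""
    X, _ = design_matrix(cohort, model.spec)
    missing = [c for c in model.coefficients.index if c not in X.columns]
    if missing:
        raise SchemaError(f"cohort lacks design column(s): {missing}", column=missing[0])
    eta = X.to_numpy(dtype=float) @ model.coefficients.to_numpy()
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    eps = np.finfo(float).tiny
    return np.clip(p, eps, 1.0 - 1e-16)
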