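"""Classification of longitudinal RDW trajectories and the pooled mixed model.

Each patient with at least ``min_obs`` (default 4) RDW measurements gets a
per-patient quadratic least-squares fit RDW = b0 + b1 t + b2 t^2 (t in days
since ARDS diagnosis). The quadratic term is checked first: if significant,
the shape is concave (b2 < 0) or convex (b2 > 0); otherwise a significant
linear term gives uptrending (b1 > 0) or downtrending (b1 < 0); otherwise
the trajectory is stable ("none"). Concave and downtrending series end
falling ("late_down"); convex and uptrending end rising ("late_up") — the
grouping used for the combined mortality comparison.

A cohort-level linear mixed model (fixed 1 + t + t^2, random per-patient
intercept and slope) is provided as a descriptive companion fit; the class
labels themselves come from the independent per-patient regressions, the
only fully specified per-patient significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_data import RDWSeries
from .errors import UnidentifiableError

CLASSES = ("concave", "down", "none", "convex", "up")

#: a coefficient in an exact (zero-residual) fit counts as significant
#: when its magnitude exceeds this
EXACT_FIT_TOL = 1e-10


@dataclass(frozen=True)
class TrajectoryClassification:
    """Per-patient quadratic fit, p-values, class label, and late direction."""

    patient_id: str
    n_obs: int
    b0: float
    b1: float
    b2: float
    p_linear: float
    p_quadratic: float
    trajectory_class: str  # concave | down | none | convex | up | excluded
    late_direction: str  # late_up | late_down | not_applicable
    degenerate_times: bool = False


def _late_direction(cls: str) -> str:
    if cls in ("up", "convex"):
        return "late_up"
    if cls in ("down", "concave"):
        return "late_down"
    return "not_applicable"


def classify_trajectory(
    series: RDWSeries, alpha: float = 0.05, min_obs: int = 4
) -> TrajectoryClassification:
    """Classify one patient's RDW series by quadratic-trend significance.

    Patients with fewer than ``min_obs`` measurements — or fewer than 3
    distinct times, where the quadratic is unidentifiable — are excluded.
    Exact fits (zero residual variance, e.g. noiseless lines) fall back to
    a magnitude rule: a coefficient is significant iff |b| > 1e-10.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.values, dtype=float)
    n = len(t)
    excluded = TrajectoryClassification(
        patient_id=series.patient_id,
        n_obs=n,
        b0=np.nan, b1=np.nan, b2=np.nan,
        p_linear=np.nan, p_quadratic=np.nan,
        trajectory_class="excluded",
        late_direction="not_applicable",
    )
    if n < min_obs:
        return excluded
    # times closer than 1e-9 of the observation span are not usably distinct
    span = max(float(t.max() - t.min()), 1.0) if n else 1.0
    n_distinct = 1 + int(np.sum(np.diff(t) / span > 1e-9)) if n else 0
    if n_distinct < 3:
        return TrajectoryClassification(
            **{**excluded.__dict__, "degenerate_times": True}
        )

    X = np.column_stack([np.ones(n), t, t**2])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - 3
    scale = float(y @ y) or 1.0
    if dof <= 0 or rss <= 1e-12 * scale:
        # exact fit: t-statistics are undefined, use the magnitude rule
        p_lin = 0.0 if abs(beta[1]) > EXACT_FIT_TOL else 1.0
        p_quad = 0.0 if abs(beta[2]) > EXACT_FIT_TOL else 1.0
    else:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tstat = beta / se
        p_lin = float(2 * stats.t.sf(abs(tstat[1]), dof))
        p_quad = float(2 * stats.t.sf(abs(tstat[2]), dof))

    if p_quad <= alpha:
        cls = "concave" if beta[2] < 0 else "convex"
    elif p_lin <= alpha:
        cls = "up" if beta[1] > 0 else "down"
    else:
        cls = "none"
    return TrajectoryClassification(
        patient_id=series.patient_id,
        n_obs=n,
        b0=float(beta[0]),
        b1=float(beta[1]),
        b2=float(beta[2]),
        p_linear=p_lin,
        p_quadratic=p_quad,
        trajectory_class=cls,
        late_direction=_late_direction(cls),
    )


@dataclass(frozen=True)
class CohortTrajectorySummary:
    """Class counts over a cohort plus the per-patient classification table."""

    counts: Mapping[str, int]
    n_excluded: int
    table: pd.DataFrame

    @property
    def n_classified(self) -> int:
        return int(sum(self.counts.values()))


def classify_cohort(
    series: Iterable[RDWSeries], alpha: float = 0.05, min_obs: int = 4
) -> CohortTrajectorySummary:
    """Classify every series and tabulate class counts (excluded separate)."""
    rows = [classify_trajectory(s, alpha=alpha, min_obs=min_obs) for s in series]
    table = pd.DataFrame([r.__dict__ for r in rows])
    counts = {c: 0 for c in CLASSES}
    n_excluded = 0
    for r in rows:
        if r.trajectory_class == "excluded":
            n_excluded += 1
        else:
            counts[r.trajectory_class] += 1
    return CohortTrajectorySummary(counts=counts, n_excluded=n_excluded, table=table)


@dataclass(frozen=True)
class MixedModelFit:
    """Cohort-level mixed model: fixed quadratic trend, random intercept+slope."""

    fixed_effects: Mapping[str, float]
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_residual: float
    n_patients: int
    n_obs: int
    converged: bool


def fit_mixed_model(series: Iterable[RDWSeries]) -> MixedModelFit:
    """Fit RDW ~ 1 + t + t^2 with per-patient random intercepts and slopes.

    Restricted maximum likelihood via statsmodels MixedLM; variance
    components are non-negative by construction. At least two patients
    (each with >= 2 observations) are required.
    """
    import statsmodels.api as sm

    series = list(series)
    usable = [s for s in series if s.n_obs >= 2]
    if len(usable) < 2:
        raise UnidentifiableError(
            "mixed-model variance components need >= 2 patients with >= 2 "
            "observations each"
        )
    long = pd.DataFrame(
        [
            (s.patient_id, t, v)
            for s in usable
            for t, v in zip(s.times, s.values)
        ],
        columns=["patient_id", "t", "rdw"],
    )
    long["t2"] = long["t"] ** 2
    exog = sm.add_constant(long[["t", "t2"]])
    exog_re = sm.add_constant(long[["t"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            long["rdw"], exog, groups=long["patient_id"], exog_re=exog_re
        )
        res = model.fit(reml=True, method=["lbfgs", "powell"])
    cov_re = np.asarray(res.cov_re)
    return MixedModelFit(
        fixed_effects={
            "intercept": float(res.fe_params["const"]),
            "time": float(res.fe_params["t"]),
            "time2": float(res.fe_params["t2"]),
        },
        var_intercept=float(cov_re[0, 0]),
        var_slope=float(cov_re[1, 1]),
        cov_intercept_slope=float(cov_re[0, 1]),
        var_residual=float(res.scale),
        n_patients=len(usable),
        n_obs=int(len(long)),
        converged=bool(getattr(res, "converged", True)),
    )
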