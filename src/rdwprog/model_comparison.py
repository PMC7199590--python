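"""Added predictive value of a biomarker: paired AUC (DeLong), continuous NRI, IDI.

All three metrics compare per-patient risks from two nested logistic models
on the same patients (apparent, in-sample performance):

* AUC — Mann–Whitney estimator; paired difference tested with DeLong's
  placement-value variance.
* Continuous (category-free) net reclassification improvement — net
  proportion of events whose risk rises under the new model plus net
  proportion of non-events whose risk falls; exact ties count in neither
  direction. The one-directional "gross" reading is available via
  ``net=False``.
* Integrated discrimination improvement — change in mean predicted risk
  among events minus the change among non-events.

Confidence intervals are asymptotic normal by default, with a seeded paired
bootstrap available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_data import CohortTable
from .errors import DegenerateLabelsError, PairingError
from .risk_models import ModelSpec, fit_logistic, predict_probability


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if labels.ndim != 1 or not np.isin(labels, (0, 1)).all():
        raise DegenerateLabelsError("labels must be a 1-d 0/1 vector")
    events = labels == 1
    if events.all() or (~events).all():
        raise DegenerateLabelsError(
            "need at least one event and one non-event"
        )
    return events, ~events


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(event score > non-event score) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    events, nonevents = _check_labels(labels)
    m, n = int(events.sum()), int(nonevents.sum())
    ranks = stats.rankdata(scores)  # mid-ranks handle ties
    return float((ranks[events].sum() - m * (m + 1) / 2) / (m * n))


def _placements(scores: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    V10[i] = P-hat(score_i beats a random non-event), one per event;
    V01[j] = P-hat(a random event beats score_j), one per non-event.
    """
    x, y = scores[events], scores[~events]
    m, n = len(x), len(y)
    tz = stats.rankdata(np.concatenate([x, y]))
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01


@dataclass(frozen=True)
class DelongResult:
    auc_base: float
    auc_new: float
    delta: float
    se: float
    ci: tuple[float, float]
    z: float
    p: float


def delong_compare(p_base, p_new, labels) -> DelongResult:
    """Paired comparison of two AUCs over the same patients (DeLong).

    The variance of the AUC difference comes from the paired covariance of
    the placement values; the two-sided p-value is normal-theory. Identical
    risk vectors give delta 0 with p = 1.
    """
    p_base = np.asarray(p_base, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    labels = np.asarray(labels)
    if p_base.shape != p_new.shape or p_base.shape != labels.shape:
        raise PairingError(
            "p_base, p_new, and labels must be equal-length vectors over the "
            "same patients"
        )
    events, nonevents = _check_labels(labels)
    m, n = int(events.sum()), int(nonevents.sum())
    if m < 2 or n < 2:
        raise DegenerateLabelsError("need >= 2 events and >= 2 non-events")
    v10_b, v01_b = _placements(p_base, events)
    v10_n, v01_n = _placements(p_new, events)
    auc_b, auc_n = float(v10_b.mean()), float(v10_n.mean())
    delta = auc_n - auc_b
    d10 = v10_n - v10_b
    d01 = v01_n - v01_b
    var = d10.var(ddof=1) / m + d01.var(ddof=1) / n
    se = float(np.sqrt(var))
    if se == 0.0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / se
        p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(
        auc_base=auc_b,
        auc_new=auc_n,
        delta=float(delta),
        se=se,
        ci=(float(delta - 1.96 * se), float(delta + 1.96 * se)),
        z=float(z),
        p=p,
    )


def delong_variance(scores, labels) -> float:
    """Single-model DeLong variance of the AUC estimate."""
    scores = np.asarray(scores, dtype=float)
    events, _ = _check_labels(labels)
    m, n = int(events.sum()), int((~events).sum())
    v10, v01 = _placements(scores, events)
    return float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)


@dataclass(frozen=True)
class NRIResult:
    total: float
    event_component: float
    nonevent_component: float
    se: float
    ci: tuple[float, float]
    z: float
    p: float
    n_events: int
    n_nonevents: int


def continuous_nri(p_base, p_new, labels, *, net: bool = True) -> NRIResult:
    """Continuous net reclassification improvement.

    Event component: net proportion of events whose predicted risk moved up
    under the new model; non-event component: net proportion of non-events
    whose risk moved down. Exact ties count in neither direction. With
    ``net=False`` the gross (up-only / down-only) proportions are summed
    instead; the SE formula is the net-version asymptotic one either way.
    """
    p_base = np.asarray(p_base, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    labels = np.asarray(labels)
    if p_base.shape != p_new.shape or p_base.shape != labels.shape:
        raise PairingError("inputs must be equal-length vectors over the same patients")
    events, nonevents = _check_labels(labels)
    d = p_new - p_base

    def props(mask: np.ndarray) -> tuple[float, float, int]:
        k = int(mask.sum())
        up = float(np.mean(d[mask] > 0))
        down = float(np.mean(d[mask] < 0))
        return up, down, k

    up_e, down_e, n_e = props(events)
    up_ne, down_ne, n_ne = props(nonevents)
    event_comp = up_e - down_e
    nonevent_comp = down_ne - up_ne
    if net:
        total = event_comp + nonevent_comp
    else:
        total = up_e + down_ne
    v_e = up_e + down_e - (up_e - down_e) ** 2
    v_ne = up_ne + down_ne - (up_ne - down_ne) ** 2
    se = float(np.sqrt(v_e / n_e + v_ne / n_ne))
    point = event_comp + nonevent_comp
    if se == 0.0:
        z, p = (0.0, 1.0) if point == 0 else (np.inf * np.sign(point), 0.0)
    else:
        z = point / se
        p = float(2 * stats.norm.sf(abs(z)))
    return NRIResult(
        total=float(total),
        event_component=float(event_comp),
        nonevent_component=float(nonevent_comp),
        se=se,
        ci=(float(total - 1.96 * se), float(total + 1.96 * se)),
        z=float(z),
        p=p,
        n_events=n_e,
        n_nonevents=n_ne,
    )


@dataclass(frozen=True)
class IDIResult:
    total: float
    mean_base_events: float
    mean_new_events: float
    mean_base_nonevents: float
    mean_new_nonevents: float
    se: float
    ci: tuple[float, float]
    z: float
    p: float
    n_events: int
    n_nonevents: int


def idi(p_base, p_new, labels) -> IDIResult:
    """Integrated discrimination improvement with the four group means.

    IDI = (mean new - mean base | events) + (mean base - mean new |
    non-events), equivalently mean(d|events) - mean(d|non-events) for
    d = p_new - p_base.
    """
    p_base = np.asarray(p_base, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    labels = np.asarray(labels)
    if p_base.shape != p_new.shape or p_base.shape != labels.shape:
        raise PairingError("inputs must be equal-length vectors over the same patients")
    events, nonevents = _check_labels(labels)
    d = p_new - p_base
    n_e, n_ne = int(events.sum()), int(nonevents.sum())
    total = float(d[events].mean() - d[nonevents].mean())
    var_e = d[events].var(ddof=1) if n_e > 1 else 0.0
    var_ne = d[nonevents].var(ddof=1) if n_ne > 1 else 0.0
    se = float(np.sqrt(var_e / n_e + var_ne / n_ne))
    if se == 0.0:
        z, p = (0.0, 1.0) if total == 0 else (np.inf * np.sign(total), 0.0)
    else:
        z = total / se
        p = float(2 * stats.norm.sf(abs(z)))
    return IDIResult(
        total=total,
        mean_base_events=float(p_base[events].mean()),
        mean_new_events=float(p_new[events].mean()),
        mean_base_nonevents=float(p_base[nonevents].mean()),
        mean_new_nonevents=float(p_new[nonevents].mean()),
        se=se,
        ci=(float(total - 1.96 * se), float(total + 1.96 * se)),
        z=float(z),
        p=p,
        n_events=n_e,
        n_nonevents=n_ne,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """One outcome's base-vs-enhanced comparison: AUCs, NRI, IDI."""

    outcome: str
    delong: DelongResult
    nri: NRIResult
    idi: IDIResult
    n_events: int
    n_nonevents: int

    @property
    def auc_base(self) -> float:
        return self.delong.auc_base

    @property
    def auc_new(self) -> float:
        return self.delong.auc_new


def bootstrap_ci(
    p_base, p_new, labels, statistic, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Seeded paired-bootstrap percentile CI for any (p_base, p_new, labels)
    statistic; resamples patients with replacement, stratified nowhere."""
    p_base = np.asarray(p_base, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if labels[idx].min() == labels[idx].max():
            continue  # degenerate resample carries no information
        vals.append(statistic(p_base[idx], p_new[idx], labels[idx]))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def compare_models(cohort: CohortTable, outcome: str = "icu") -> ComparisonResult:
    """Fit base and enhanced models for one outcome and compare them.

    Both models are fitted on the full cohort and evaluated on their own
    in-sample predicted probabilities (apparent performance).
    """
    base = fit_logistic(cohort, ModelSpec(outcome=outcome, include_rdw=False))
    new = fit_logistic(cohort, ModelSpec(outcome=outcome, include_rdw=True))
    p_base = predict_probability(base, cohort)
    p_new = predict_probability(new, cohort)
    from .risk_models import OUTCOMES

    labels = cohort.to_frame()[OUTCOMES[outcome]].to_numpy(dtype=int)
    d = delong_compare(p_base, p_new, labels)
    return ComparisonResult(
        outcome=outcome,
        delong=d,
        nri=continuous_nri(p_base, p_new, labels),
        idi=idi(p_base, p_new, labels),
        n_events=int(labels.sum()),
        n_nonevents=int((1 - labels).sum()),
    )
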