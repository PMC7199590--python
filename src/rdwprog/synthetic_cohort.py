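"""Synthetic ICU cohort generator calibrated to the published ARDS summary tables.

Generates patient-level cohorts with the statistical structure the analysis
assumes: covariates drawn independently from moment-matched truncated
normals (so the truncated distributions reproduce the published cohort
means/SDs exactly), ICU death from a logistic model whose slope
coefficients default to the published enhanced-model odds ratios and whose
intercept is calibrated by bisection to the published 35.5% ICU mortality,
nested in-hospital and 90-day outcomes, and per-patient longitudinal RDW
series drawn from a five-class trajectory mixture (concave / down / none /
convex / up) with class-appropriate quadratic trend coefficients.

Randomness is organised in named substreams of a single master seed:
each covariate, each outcome layer, and each patient's RDW series has its
own stream, so enlarging the cohort does not perturb earlier patients'
draws and identical (config, seed) pairs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .cohort_data import CohortTable, PatientRecord, RDWSeries
from .errors import CalibrationError, ConfigError

TRAJECTORY_CLASSES = ("concave", "down", "none", "convex", "up")

#: published enhanced-model odds ratios, stored as log-odds-ratios
DEFAULT_COEFFICIENTS = {
    "age": math.log(1.05),
    "male": math.log(1.53),
    "comorbid_1": math.log(1.02),
    "comorbid_2": math.log(0.88),
    "comorbid_3plus": math.log(0.84),
    "sofa": math.log(1.08),
    "pf_ratio": math.log(0.995),
    "rdw_baseline": math.log(1.22),
}

#: class shares among the 272 patients with >= 4 RDW measurements
DEFAULT_TRAJECTORY_MIXTURE = {
    "concave": 26 / 272,
    "down": 24 / 272,
    "none": 174 / 272,
    "convex": 29 / 272,
    "up": 19 / 272,
}

#: published in-hospital mortality within each trajectory class
DEFAULT_CLASS_MORTALITY = {
    "concave": 8 / 26,
    "down": 8 / 24,
    "none": 70 / 174,
    "convex": 14 / 29,
    "up": 11 / 19,
}

#: (b1 range %/day, b2 range %/day^2) per class; None-range means exactly 0
DEFAULT_CLASS_COEF_RANGES = {
    "concave": ((0.3, 0.6), (-0.045, -0.02)),
    "down": ((-0.5, -0.2), None),
    "none": (None, None),
    "convex": ((-0.6, -0.3), (0.02, 0.045)),
    "up": ((0.2, 0.5), None),
}


@dataclass(frozen=True)
class TrajectoryParams:
    """Per-class RDW trend generation parameters.

    b1 is the linear trend in %/day, b2 the quadratic trend in %/day^2;
    a ``None`` range pins the coefficient at exactly zero. Measurement
    counts mix two stay types: with probability ``prop_adequate`` the
    patient is adequately sampled (near-daily CBCs: 4 +
    Poisson(extra_measurements_lambda) measurements), otherwise a short
    stay with 2-3 measurements that the trajectory analysis will exclude.
    Times are uniform over [0, followup_days]; values are clipped at
    rdw_floor so generated RDW stays physiologically positive.
    """

    coef_ranges: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COEF_RANGES)
    )
    noise_sd: float = 0.3
    followup_days: float = 14.0
    prop_adequate: float = 272 / 318
    extra_measurements_lambda: float = 6.0
    rdw_floor: float = 11.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0", field="noise_sd")
        if self.followup_days <= 0:
            raise ConfigError("followup_days must be > 0", field="followup_days")
        if self.rdw_floor <= 0:
            raise ConfigError("rdw_floor must be > 0", field="rdw_floor")
        if not 0 <= self.prop_adequate <= 1:
            raise ConfigError("prop_adequate must be in [0, 1]", field="prop_adequate")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic cohort.

    Covariate parameters are the *target* mean/SD of each truncated
    distribution (the parent normal is solved internally so the truncated
    moments match). Outcome coefficients are log-odds-ratios on the scale
    of the fitted enhanced model. ``mortality_mode`` selects how
    in-hospital death is generated: ``"model"`` adds an extra conditional
    death probability on top of model-driven ICU death, while
    ``"class_linked"`` draws in-hospital death from the class-conditional
    published rates (the two structures cannot both be exactly generative
    at once).
    """

    n: int
    seed: int = 0
    age_mean: float = 58.6
    age_sd: float = 18.3
    age_bounds: tuple[float, float] = (18.0, 100.0)
    male_prop: float = 165 / 318
    sofa_mean: float = 10.1
    sofa_sd: float = 4.6
    sofa_bounds: tuple[float, float] = (0.0, 24.0)
    pf_mean: float = 140.8
    pf_sd: float = 73.3
    pf_bounds: tuple[float, float] = (40.0, 400.0)
    rdw_mean: float = 15.3
    rdw_sd: float = 2.3
    rdw_bounds: tuple[float, float] = (11.0, 30.0)
    comorbidity_probs: tuple[float, float, float, float] = (0.30, 0.30, 0.20, 0.20)
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    target_icu_rate: float = 0.355
    # chosen so P(hosp) = icu + (1 - icu) * q_hosp = 0.440
    q_hosp: float = (0.440 - 0.355) / (1 - 0.355)
    q_90: float = 0.05
    mortality_mode: str = "model"
    trajectory_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORY_MIXTURE)
    )
    class_mortality: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MORTALITY)
    )
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0", field="n")
        for name in ("age_sd", "sofa_sd", "pf_sd", "rdw_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0", field=name)
        for name in ("male_prop", "target_icu_rate", "q_hosp", "q_90"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}", field=name)
        if not 0 < self.target_icu_rate < 1:
            raise ConfigError("target_icu_rate must be in (0, 1)", field="target_icu_rate")
        if abs(sum(self.comorbidity_probs) - 1) > 1e-9 or min(self.comorbidity_probs) < 0:
            raise ConfigError(
                "comorbidity_probs must be non-negative and sum to 1",
                field="comorbidity_probs",
            )
        mix = dict(self.trajectory_mixture)
        if set(mix) != set(TRAJECTORY_CLASSES):
            raise ConfigError(
                f"trajectory_mixture must have keys {TRAJECTORY_CLASSES}",
                field="trajectory_mixture",
            )
        if abs(sum(mix.values()) - 1) > 1e-9 or min(mix.values()) < 0:
            raise ConfigError(
                "trajectory_mixture must be a probability vector summing to 1",
                field="trajectory_mixture",
            )
        for cls, rate in self.class_mortality.items():
            if not 0 <= rate <= 1:
                raise ConfigError(
                    f"class_mortality[{cls!r}] must be in [0, 1]", field="class_mortality"
                )
        if self.mortality_mode not in ("model", "class_linked"):
            raise ConfigError(
                "mortality_mode must be 'model' or 'class_linked'",
                field="mortality_mode",
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = dict(self.coefficients)
        d["trajectory_mixture"] = dict(self.trajectory_mixture)
        d["class_mortality"] = dict(self.class_mortality)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        data = dict(data)
        if "n" not in data:
            raise ConfigError("config missing required field 'n'", field="n")
        if "trajectory" in data and isinstance(data["trajectory"], Mapping):
            traj = dict(data["trajectory"])
            if "coef_ranges" in traj:
                traj["coef_ranges"] = {
                    k: tuple(tuple(r) if r is not None else None for r in v)
                    for k, v in traj["coef_ranges"].items()
                }
            data["trajectory"] = TrajectoryParams(**traj)
        for name in ("age_bounds", "sofa_bounds", "pf_bounds", "rdw_bounds",
                     "comorbidity_probs"):
            if name in data:
                data[name] = tuple(data[name])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}",
                              field=sorted(unknown)[0])
        return cls(**data)


@lru_cache(maxsize=64)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) such that N(mu, sigma) truncated to [lo, hi]
    has exactly the requested mean and SD; returns a frozen truncnorm."""

    def moments(x):
        mu, s = x
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(moments, [mean, sd])
    if not sol.success:
        raise ConfigError(
            f"cannot moment-match truncated normal: mean={mean}, sd={sd}, "
            f"bounds=({lo}, {hi})"
        )
    mu, s = sol.x
    a, b = (lo - mu) / s, (hi - mu) / s
    return stats.truncnorm(a, b, loc=mu, scale=s)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng([seed, *key])


def _draw_covariates(config: GeneratorConfig, n: int, seed: int, stream: int = 0):
    """Draw the covariate block as a dict of arrays, one substream per column.

    Uses inverse-CDF sampling (one uniform per patient per covariate) so the
    first n draws are identical whenever the cohort is enlarged.
    """
    dists = {
        "age": _matched_truncnorm(config.age_mean, config.age_sd, *config.age_bounds),
        "sofa": _matched_truncnorm(config.sofa_mean, config.sofa_sd, *config.sofa_bounds),
        "pf_ratio": _matched_truncnorm(config.pf_mean, config.pf_sd, *config.pf_bounds),
        "rdw_baseline": _matched_truncnorm(
            config.rdw_mean, config.rdw_sd, *config.rdw_bounds
        ),
    }
    cov: dict[str, np.ndarray] = {}
    for k, name in enumerate(["age", "sofa", "pf_ratio", "rdw_baseline"]):
        u = _rng(seed, stream, k).uniform(size=n)
        cov[name] = np.asarray(dists[name].ppf(u), dtype=float)
    cov["sofa"] = np.clip(np.rint(cov["sofa"]), *config.sofa_bounds).astype(int)
    cov["male"] = (_rng(seed, stream, 4).uniform(size=n) < config.male_prop).astype(int)
    u = _rng(seed, stream, 5).uniform(size=n)
    edges = np.cumsum(config.comorbidity_probs)
    cov["comorbidity_category"] = np.searchsorted(edges, u, side="right").clip(0, 3)
    return cov


def _linear_predictor(cov: Mapping[str, np.ndarray], coefficients: Mapping[str, float],
                      include_rdw: bool = True) -> np.ndarray:
    cat = cov["comorbidity_category"]
    eta = (
        coefficients.get("age", 0.0) * cov["age"]
        + coefficients.get("male", 0.0) * cov["male"]
        + coefficients.get("comorbid_1", 0.0) * (cat == 1)
        + coefficients.get("comorbid_2", 0.0) * (cat == 2)
        + coefficients.get("comorbid_3plus", 0.0) * (cat == 3)
        + coefficients.get("sofa", 0.0) * cov["sofa"]
        + coefficients.get("pf_ratio", 0.0) * cov["pf_ratio"]
    )
    if include_rdw:
        eta = eta + coefficients.get("rdw_baseline", 0.0) * cov["rdw_baseline"]
    return np.asarray(eta, dtype=float)


def calibrate_intercept(
    config: GeneratorConfig,
    target_rate: float | None = None,
    seed: int | None = None,
    tol: float = 1e-3,
) -> float:
    """Find the logistic intercept that hits the target marginal event rate.

    Draws a large covariate sample (>= 10 n, at least 10,000) from the
    configured distributions and bisects the intercept over [-20, 20] until
    the mean of logistic(b0 + b.x) over the sample is within ``tol`` of the
    target rate.
    """
    if target_rate is None:
        target_rate = config.target_icu_rate
    if not 0 < target_rate < 1:
        raise CalibrationError(f"target rate must be in (0, 1), got {target_rate}")
    if seed is None:
        seed = config.seed
    m = max(10 * config.n, 10_000)
    cov = _draw_covariates(config, m, seed, stream=9)
    eta = _linear_predictor(cov, config.coefficients)

    def rate(b0: float) -> float:
        return float(np.mean(expit(b0 + eta)))

    lo, hi = -20.0, 20.0
    if not rate(lo) <= target_rate <= rate(hi):
        raise CalibrationError(
            f"target rate {target_rate} unattainable within intercept bounds "
            f"[{lo}, {hi}] (degenerate covariates?)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) <= tol:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to reach the target rate")


def generate_rdw_series(
    trajectory_class: str,
    params: TrajectoryParams,
    seed,
    *,
    patient_id: str = "p1",
    b0: float = 15.3,
    n_obs: int | None = None,
) -> RDWSeries:
    """Draw one patient's RDW series for a given trajectory class.

    The quadratic trend RDW(t) = b0 + b1 t + b2 t^2 + N(0, noise_sd) has
    coefficient signs fixed by the class: concave b2 < 0, convex b2 > 0,
    up b1 > 0 (b2 = 0), down b1 < 0 (b2 = 0), none b1 = b2 = 0. Values are
    clipped at the configured floor so they stay positive. ``seed`` may be
    an int or a numpy Generator.
    """
    if trajectory_class not in TRAJECTORY_CLASSES:
        raise ConfigError(
            f"unknown trajectory class {trajectory_class!r}", field="trajectory_class"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b1_range, b2_range = params.coef_ranges[trajectory_class]
    b1 = 0.0 if b1_range is None else rng.uniform(*b1_range)
    b2 = 0.0 if b2_range is None else rng.uniform(*b2_range)
    if n_obs is None:
        if rng.uniform() < params.prop_adequate:
            n_obs = 4 + int(rng.poisson(params.extra_measurements_lambda))
        else:
            n_obs = int(rng.integers(2, 4))
    if n_obs < 1:
        raise ConfigError("n_obs must be >= 1", field="n_obs")
    # strictly increasing times; jitter resolves ties from rounding
    t = np.sort(rng.uniform(0.0, params.followup_days, size=n_obs))
    while np.any(np.diff(t) <= 1e-9):
        t = np.sort(rng.uniform(0.0, params.followup_days, size=n_obs))
    values = b0 + b1 * t + b2 * t**2
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n_obs)
    values = np.maximum(values, params.rdw_floor)
    return RDWSeries(patient_id=patient_id, times=tuple(t), values=tuple(values))


def generate_cohort(
    config: GeneratorConfig, *, with_series: bool = True
) -> tuple[CohortTable, tuple[RDWSeries, ...]]:
    """Generate a full synthetic cohort and its longitudinal RDW series.

    Covariates are independent moment-matched truncated draws; ICU death is
    Bernoulli(logistic(b0 + b.x)) with the intercept calibrated to the
    configured target rate; in-hospital and 90-day deaths are nested
    supersets. Each patient is assigned a trajectory class from the mixture
    and, when ``with_series`` is true, an RDW series whose intercept is the
    patient's baseline RDW. In ``class_linked`` mortality mode in-hospital
    death is drawn from the class-conditional rates instead, with ICU death
    a thinned subset preserving the configured ICU/in-hospital ratio.
    """
    n, seed = config.n, config.seed
    if n == 0:
        return CohortTable(records=()), ()
    cov = _draw_covariates(config, n, seed, stream=0)

    classes = np.array(TRAJECTORY_CLASSES)
    mix = np.array([config.trajectory_mixture[c] for c in TRAJECTORY_CLASSES])
    u_cls = _rng(seed, 2, 0).uniform(size=n)
    cls_idx = np.searchsorted(np.cumsum(mix), u_cls, side="right").clip(0, 4)
    patient_class = classes[cls_idx]

    u_icu = _rng(seed, 1, 0).uniform(size=n)
    u_hosp = _rng(seed, 1, 1).uniform(size=n)
    u_90 = _rng(seed, 1, 2).uniform(size=n)
    if config.mortality_mode == "model":
        b0 = calibrate_intercept(config)
        p = expit(b0 + _linear_predictor(cov, config.coefficients))
        icu = u_icu < p
        hosp = icu | (u_hosp < config.q_hosp)
    else:
        rates = np.array([config.class_mortality[c] for c in patient_class])
        hosp = u_hosp < rates
        # thin to keep the ICU / in-hospital marginal ratio
        overall_hosp = float(
            sum(
                config.trajectory_mixture[c] * config.class_mortality[c]
                for c in TRAJECTORY_CLASSES
            )
        )
        ratio = min(1.0, config.target_icu_rate / max(overall_hosp, 1e-12))
        icu = hosp & (u_icu < ratio)
    d90 = hosp | (u_90 < config.q_90)

    records = tuple(
        PatientRecord(
            patient_id=f"p{i + 1:05d}",
            age=float(cov["age"][i]),
            sex="male" if cov["male"][i] else "female",
            comorbidity_category=("0", "1", "2", "3plus")[cov["comorbidity_category"][i]],
            sofa=int(cov["sofa"][i]),
            pf_ratio=float(cov["pf_ratio"][i]),
            rdw_baseline=float(cov["rdw_baseline"][i]),
            icu_death=bool(icu[i]),
            hosp_death=bool(hosp[i]),
            death_90d=bool(d90[i]),
        )
        for i in range(n)
    )
    cohort = CohortTable(records=records)
    if not with_series:
        return cohort, ()
    series = tuple(
        generate_rdw_series(
            patient_class[i],
            config.trajectory,
            _rng(seed, 3, i),
            patient_id=records[i].patient_id,
            b0=records[i].rdw_baseline,
        )
        for i in range(n)
    )
    return cohort, series
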