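"""Calibration, determinism, and statistical structure of the cohort generator."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from rdwprog import (
    calibrate_intercept,
    generate_cohort,
    generate_rdw_series,
)
from rdwprog.errors import ConfigError
from rdwprog.synthetic_cohort import (
    DEFAULT_COEFFICIENTS,
    GeneratorConfig,
    TrajectoryParams,
    _matched_truncnorm,
)


class TestConfigValidation:
    def test_bad_mixture_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(
                n=10,
                trajectory_mixture={
                    "concave": 0.5, "down": 0.5, "none": 0.5,
                    "convex": 0.0, "up": 0.0,
                },
            )

    def test_missing_n_rejected(self):
        with pytest.raises(ConfigError) as exc:
            GeneratorConfig.from_dict({"seed": 1})
        assert exc.value.field == "n"

    def test_negative_n_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n=-1)

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig.from_dict({"n": 5, "banana": 1})


class TestMomentMatchedTruncation:
    @pytest.mark.parametrize(
        "mean,sd,lo,hi",
        [(58.6, 18.3, 18, 100), (140.8, 73.3, 40, 400), (15.3, 2.3, 11, 30)],
    )
    def test_truncated_moments_hit_targets(self, mean, sd, lo, hi):
        dist = _matched_truncnorm(mean, sd, lo, hi)
        m, v = dist.stats(moments="mv")
        assert float(m) == pytest.approx(mean, abs=1e-6)
        assert float(np.sqrt(v)) == pytest.approx(sd, abs=1e-6)


class TestCalibrateIntercept:
    def test_zero_slopes_symmetric_target(self):
        cfg = GeneratorConfig(
            n=100, seed=3, coefficients={k: 0.0 for k in DEFAULT_COEFFICIENTS}
        )
        assert calibrate_intercept(cfg, 0.5) == pytest.approx(0.0, abs=0.02)

    def test_zero_slopes_closed_form(self):
        cfg = GeneratorConfig(
            n=100, seed=3, coefficients={k: 0.0 for k in DEFAULT_COEFFICIENTS}
        )
        b0 = calibrate_intercept(cfg, 0.355)
        assert b0 == pytest.approx(logit(0.355), abs=0.02)

    def test_default_coefficients_monte_carlo(self):
        """At n=50,000 the simulated ICU death rate matches the target."""
        cfg = GeneratorConfig(n=50_000, seed=11)
        cohort, _ = generate_cohort(cfg, with_series=False)
        rate = np.mean([r.icu_death for r in cohort])
        assert rate == pytest.approx(0.355, abs=0.01)

    def test_intercept_only_rate(self):
        """Zero slopes + logit(0.5) intercept give a 50% death rate."""
        coeffs = {k: 0.0 for k in DEFAULT_COEFFICIENTS}
        cfg = GeneratorConfig(n=10_000, seed=5, coefficients=coeffs, target_icu_rate=0.5)
        cohort, _ = generate_cohort(cfg, with_series=False)
        rate = np.mean([r.icu_death for r in cohort])
        assert rate == pytest.approx(0.5, abs=0.015)


class TestGenerateCohort:
    def test_empty_cohort(self):
        cohort, series = generate_cohort(GeneratorConfig(n=0))
        assert len(cohort) == 0 and series == ()

    def test_icu_rate_within_binomial_bounds(self, default_cohort):
        cohort, _ = default_cohort
        rate = np.mean([r.icu_death for r in cohort])
        # 99% binomial bounds around the target at n=318
        half = 2.576 * math.sqrt(0.355 * 0.645 / 318)
        assert abs(rate - 0.355) < half

    def test_determinism_bit_identical(self):
        cfg = GeneratorConfig(n=40, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a == b

    def test_outcome_nesting_holds(self, default_cohort):
        cohort, _ = default_cohort
        for r in cohort:
            assert (not r.icu_death) or r.hosp_death
            assert (not r.hosp_death) or r.death_90d

    def test_earlier_patients_stable_when_enlarged(self):
        small, _ = generate_cohort(GeneratorConfig(n=20, seed=13), with_series=False)
        big, _ = generate_cohort(GeneratorConfig(n=40, seed=13), with_series=False)
        for a, b in zip(small, big):
            assert a.age == b.age
            assert a.rdw_baseline == b.rdw_baseline
            assert a.sex == b.sex

    def test_class_linked_mode_mortality_gradient(self):
        """Class-linked in-hospital deaths follow the class-conditional rates."""
        cfg = GeneratorConfig(n=20_000, seed=21, mortality_mode="class_linked")
        cohort, series = generate_cohort(cfg)
        frame = cohort.to_frame()
        # mixture-weighted class mortality: 111 deaths / 272 classified
        assert frame["hosp_death"].mean() == pytest.approx(111 / 272, abs=0.02)
        # nesting holds and ICU death is thinned to its own marginal target
        assert (frame["icu_death"] <= frame["hosp_death"]).all()
        assert frame["icu_death"].mean() == pytest.approx(0.355, abs=0.02)


class TestGenerateRdwSeries:
    params = TrajectoryParams()

    def test_none_class_zero_noise_is_constant(self):
        p = TrajectoryParams(noise_sd=0.0)
        s = generate_rdw_series("none", p, seed=1, b0=14.0, n_obs=6)
        assert np.allclose(s.values, 14.0)

    def test_exact_line(self):
        """Noiseless up-class series is exactly b0 + b1 t."""
        ranges = dict(self.params.coef_ranges)
        ranges["up"] = ((0.2, 0.2), None)
        p = TrajectoryParams(noise_sd=0.0, coef_ranges=ranges)
        s = generate_rdw_series("up", p, seed=2, b0=14.0, n_obs=10)
        t = np.array(s.times)
        assert np.allclose(np.array(s.values), 14.0 + 0.2 * t)

    @pytest.mark.parametrize("cls,sign_b1,sign_b2", [
        ("concave", +1, -1), ("convex", -1, +1), ("up", +1, 0), ("down", -1, 0),
        ("none", 0, 0),
    ])
    def test_coefficient_signs_respect_class(self, cls, sign_b1, sign_b2):
        p = TrajectoryParams(noise_sd=0.0, rdw_floor=0.1)
        s = generate_rdw_series(cls, p, seed=3, b0=15.0, n_obs=8)
        t = np.array(s.times)
        X = np.column_stack([np.ones_like(t), t, t**2])
        b = np.linalg.lstsq(X, np.array(s.values), rcond=None)[0]
        if sign_b1:
            assert np.sign(b[1]) == sign_b1
        else:
            assert abs(b[1]) < 1e-9
        if sign_b2:
            assert np.sign(b[2]) == sign_b2
        else:
            assert abs(b[2]) < 1e-9

    def test_values_respect_floor(self):
        ranges = dict(self.params.coef_ranges)
        ranges["down"] = ((-5.0, -5.0), None)  # crash far below the floor
        p = TrajectoryParams(noise_sd=0.0, coef_ranges=ranges, rdw_floor=11.0)
        s = generate_rdw_series("down", p, seed=4, b0=12.0, n_obs=10)
        assert min(s.values) >= 11.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigError):
            generate_rdw_series("spiral", self.params, seed=5)
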