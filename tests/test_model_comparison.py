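"""AUC, DeLong comparison, continuous NRI, and IDI against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdwprog import auc, compare_models, continuous_nri, delong_compare, idi
from rdwprog.errors import DegenerateLabelsError, PairingError
from rdwprog.model_comparison import delong_variance


def pair_counting_auc(scores, labels):
    """Brute-force oracle: mean over event x non-event pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    ev = scores[labels == 1]
    ne = scores[labels == 0]
    total = 0.0
    for x in ev:
        for y in ne:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(ev) * len(ne))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_hand_counted_example(self):
        assert auc([0.8, 0.7, 0.6, 0.5, 0.4], [1, 0, 1, 0, 0]) == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(4, 60))
        labels = np.array(
            data.draw(
                st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                    lambda ls: 0 < sum(ls) < len(ls)
                )
            )
        )
        # coarse grid of scores forces plenty of ties
        scores = np.array(
            data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n)),
            dtype=float,
        ) / 8.0
        assert auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )


class TestDelong:
    def test_identical_models_null_result(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        labels = (rng.uniform(size=30) < 0.4).astype(int)
        labels[:2] = [0, 1]  # both classes present
        r = delong_compare(p, p, labels)
        assert r.delta == 0.0 and r.p == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            delong_compare([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])

    def test_se_close_to_bootstrap_oracle(self):
        """DeLong SE of the AUC difference within 15% of a 10,000-replicate
        paired bootstrap on a seeded n=50 fixture."""
        rng = np.random.default_rng(7)
        n = 50
        labels = np.array([1] * 20 + [0] * 30)
        signal = labels * 0.8
        p_base = 1 / (1 + np.exp(-(signal + rng.normal(0, 1, n))))
        p_new = 1 / (1 + np.exp(-(1.3 * signal + rng.normal(0, 1, n))))
        r = delong_compare(p_base, p_new, labels)

        boot = np.random.default_rng(8)
        deltas = []
        while len(deltas) < 10_000:
            idx = boot.integers(0, n, size=n)
            ls = labels[idx]
            if ls.min() == ls.max():
                continue
            deltas.append(auc(p_new[idx], ls) - auc(p_base[idx], ls))
        boot_se = np.std(deltas, ddof=1)
        assert r.se == pytest.approx(boot_se, rel=0.15)

    def test_matches_reference_implementation_on_frozen_fixture(self):
        """Agreement with an independent reference implementation of the
        paired DeLong test (values computed once from this seeded fixture)."""
        rng = np.random.default_rng(7)
        n = 80
        labels = (rng.uniform(size=n) < 0.4).astype(int)
        labels[:2] = [0, 1]
        eta = 1.0 * labels + rng.normal(0, 1, n)
        s1 = eta + rng.normal(0, 0.7, n)
        s2 = 0.8 * eta + rng.normal(0, 0.9, n)
        r = delong_compare(s1, s2, labels)
        assert r.auc_base == pytest.approx(0.8471954, abs=1e-6)
        assert r.auc_new == pytest.approx(0.8194713, abs=1e-6)
        assert r.p == pytest.approx(0.608753, abs=1e-5)

    def test_calibrated_under_fixed_scores_null(self):
        """With two fixed score vectors of equal population AUC (the setting
        the test's variance theory assumes), the 5% rejection rate is
        nominal over 1,000 seeded replicates."""
        rng = np.random.default_rng(99)
        rej = 0
        reps, n = 1000, 200
        for _ in range(reps):
            y = (rng.uniform(size=n) < 0.4).astype(int)
            while y.min() == y.max():
                y = (rng.uniform(size=n) < 0.4).astype(int)
            eta = 1.2 * y + rng.normal(0, 1, n)
            s1 = eta + rng.normal(0, 0.8, n)
            s2 = eta + rng.normal(0, 0.8, n)
            rej += delong_compare(s1, s2, y).p < 0.05
        assert 0.03 < rej / reps < 0.07

    def test_reduces_to_single_model_variance_at_vanishing_delta(self):
        """Comparing a model against itself plus vanishing noise recovers the
        single-model DeLong AUC variance."""
        rng = np.random.default_rng(3)
        n = 120
        labels = (rng.uniform(size=n) < 0.4).astype(int)
        labels[:2] = [0, 1]
        p = rng.uniform(size=n)
        var_single = delong_variance(p, labels)
        noise = rng.normal(0, 1, size=n)
        for eps in (1e-4, 1e-6):
            r = delong_compare(p, 1 / (1 + np.exp(-(np.log(p / (1 - p)) + eps * noise))), labels)
            # variance of the *difference* vanishes...
            assert r.se**2 < 1e-3 * var_single
        # ...while each model's own AUC variance stays at the single-model value
        assert delong_variance(p + 1e-6 * noise, labels) == pytest.approx(
            var_single, rel=1e-3
        )


class TestNri:
    def test_identity(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        r = continuous_nri(p, p, labels)
        assert r.total == 0.0 and r.p == 1.0

    def test_hand_enumerated_example(self):
        """Events both move up, non-events split one up one down."""
        p_base = np.array([0.3, 0.4, 0.2, 0.6])
        p_new = np.array([0.4, 0.5, 0.1, 0.7])
        labels = np.array([1, 1, 0, 0])
        r = continuous_nri(p_base, p_new, labels)
        assert r.event_component == pytest.approx(1.0)
        assert r.nonevent_component == pytest.approx(0.0)
        assert r.total == pytest.approx(1.0)

    def test_ties_count_in_neither_direction(self):
        p_base = np.array([0.3, 0.4, 0.2, 0.6])
        p_new = np.array([0.3, 0.5, 0.2, 0.5])  # one event tied, one nonevent tied
        labels = np.array([1, 1, 0, 0])
        r = continuous_nri(p_base, p_new, labels)
        assert r.event_component == pytest.approx(0.5)
        assert r.nonevent_component == pytest.approx(0.5)

    def test_gross_variant_sums_up_proportions(self):
        p_base = np.array([0.3, 0.4, 0.2, 0.6])
        p_new = np.array([0.4, 0.3, 0.1, 0.7])
        labels = np.array([1, 1, 0, 0])
        r = continuous_nri(p_base, p_new, labels, net=False)
        assert r.total == pytest.approx(0.5 + 0.5)  # up-events + down-nonevents


class TestIdi:
    def test_identity(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        r = idi(p, p, labels)
        assert r.total == 0.0 and r.p == 1.0

    def test_hand_means_example(self):
        p_base = np.array([0.3, 0.4, 0.2, 0.6])
        p_new = np.array([0.45, 0.45, 0.3, 0.5])
        labels = np.array([1, 1, 0, 0])
        r = idi(p_base, p_new, labels)
        assert r.total == pytest.approx((0.45 - 0.35) - (0.40 - 0.40))
        assert r.mean_base_events == pytest.approx(0.35)
        assert r.mean_new_events == pytest.approx(0.45)


class TestJointProperties:
    def setup_method(self):
        rng = np.random.default_rng(17)
        self.n = 80
        self.labels = (rng.uniform(size=self.n) < 0.35).astype(int)
        self.labels[:2] = [0, 1]
        self.p_base = rng.uniform(0.05, 0.95, size=self.n)
        self.p_new = np.clip(
            self.p_base + rng.normal(0, 0.1, size=self.n), 0.01, 0.99
        )

    def test_antisymmetry_under_model_swap(self):
        d1 = delong_compare(self.p_base, self.p_new, self.labels)
        d2 = delong_compare(self.p_new, self.p_base, self.labels)
        assert d1.delta == pytest.approx(-d2.delta, abs=1e-12)
        n1 = continuous_nri(self.p_base, self.p_new, self.labels)
        n2 = continuous_nri(self.p_new, self.p_base, self.labels)
        assert n1.total == pytest.approx(-n2.total, abs=1e-12)
        i1 = idi(self.p_base, self.p_new, self.labels)
        i2 = idi(self.p_new, self.p_base, self.labels)
        assert i1.total == pytest.approx(-i2.total, abs=1e-12)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(5)
        perm = rng.permutation(self.n)
        n1 = continuous_nri(self.p_base, self.p_new, self.labels)
        n2 = continuous_nri(self.p_base[perm], self.p_new[perm], self.labels[perm])
        assert n1.total == pytest.approx(n2.total, abs=1e-12)
        i1 = idi(self.p_base, self.p_new, self.labels)
        i2 = idi(self.p_base[perm], self.p_new[perm], self.labels[perm])
        assert i1.total == pytest.approx(i2.total, abs=1e-12)

    def test_components_bounded_and_cis_contain_estimates(self):
        d = delong_compare(self.p_base, self.p_new, self.labels)
        n = continuous_nri(self.p_base, self.p_new, self.labels)
        i = idi(self.p_base, self.p_new, self.labels)
        assert -1 <= n.event_component <= 1
        assert -1 <= n.nonevent_component <= 1
        assert -2 <= n.total <= 2
        assert d.ci[0] <= d.delta <= d.ci[1]
        assert n.ci[0] <= n.total <= n.ci[1]
        assert i.ci[0] <= i.total <= i.ci[1]


class TestCompareModels:
    def test_invariant_identities_on_synthetic_cohort(self, default_cohort):
        cohort, _ = default_cohort
        c = compare_models(cohort, "icu")
        assert c.delong.delta == pytest.approx(c.auc_new - c.auc_base, abs=1e-12)
        assert c.nri.total == pytest.approx(
            c.nri.event_component + c.nri.nonevent_component, abs=1e-12
        )
        assert c.idi.total == pytest.approx(
            (c.idi.mean_new_events - c.idi.mean_base_events)
            + (c.idi.mean_base_nonevents - c.idi.mean_new_nonevents),
            abs=1e-12,
        )
        # the enhanced model nests the base model, so in-sample AUC cannot drop
        assert c.auc_new >= c.auc_base - 1e-9
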