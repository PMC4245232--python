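"""Random-effects pooling, heterogeneity estimation and estimate selection."""

import numpy as np
import pytest

import medimeta as mm
from medimeta.errors import DesignError, DomainError, EmptyInputError
from conftest import make_estimates

# Independent cross-check values computed with metafor 4.8-0 (rma, method="EB")
# on the two fixtures below.
FIXTURE_A = [("s1", 0.12, 0.04), ("s2", -0.05, 0.09), ("s3", 0.30, 0.05),
             ("s4", 0.22, 0.11), ("s5", 0.01, 0.03), ("s6", 0.45, 0.15)]
METAFOR_A = dict(tau2=0.0, tau2_se=0.0360709156, pooled=0.1309649544,
                 se=0.0974962609, ci_low=-0.0601242055, ci_high=0.3220541143,
                 p=0.1791807377, Q=2.1767050728, p_Q=0.8241935668)
FIXTURE_B = [("s1", 0.5, 0.02), ("s2", -0.2, 0.05), ("s3", 0.9, 0.03),
             ("s4", 0.1, 0.04)]
METAFOR_B = dict(tau2=0.1909718918, tau2_se=0.1840529095, pooled=0.3407123826,
                 se=0.2373909523, Q=18.2467532468, p_Q=0.0003911982)


def grid_tau2_oracle(y, v, upper=10.0, step=1e-4):
    """Brute-force root of the empirical-Bayes estimating equation."""
    y, v = np.asarray(y, float), np.asarray(v, float)
    k = len(y)
    grid = np.arange(0.0, upper, step)
    w = 1.0 / (v[:, None] + grid[None, :])
    mu = (w * y[:, None]).sum(axis=0) / w.sum(axis=0)
    F = (w * (y[:, None] - mu[None, :]) ** 2).sum(axis=0) - (k - 1)
    if F[0] <= 0:
        return 0.0
    return float(grid[np.argmin(np.abs(F))])


class TestSelectMostPrecise:
    def test_minimum_variance_wins(self):
        ests = make_estimates(
            [("s1", 0.2, 0.04), ("s1", 0.3, 0.01), ("s2", 0.1, 0.05)],
            outcomes=["MWM", "FST", "OF"],
        )
        chosen = mm.select_most_precise(ests)
        assert {(e.study_id, e.v) for e in chosen} == {("s1", 0.01), ("s2", 0.05)}

    def test_single_estimate_is_identity(self):
        ests = make_estimates([("s1", 0.2, 0.04)])
        assert mm.select_most_precise(ests) == ests

    def test_tie_broken_by_declared_outcome_order(self):
        ests = make_estimates(
            [("s1", 0.1, 0.02), ("s1", 0.9, 0.02)], outcomes=["FST", "MWM"]
        )
        chosen = mm.select_most_precise(ests, primary_outcome_order=["MWM", "FST"])
        assert chosen[0].outcome == "MWM"
        # without a declared order, ties fall back to the lexical label
        chosen = mm.select_most_precise(ests)
        assert chosen[0].outcome == "FST"

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            mm.select_most_precise([])


class TestEbTau2:
    def test_identical_estimates_give_zero(self):
        tau2, _ = mm.eb_tau2(make_estimates([("a", 0.5, 0.1), ("b", 0.5, 0.2), ("c", 0.5, 0.05)]))
        assert tau2 == 0.0

    def test_two_study_root_matches_grid_oracle(self):
        # y = {0, 2}, v = {1, 1}: the estimating equation solves to tau2 = 1
        ests = make_estimates([("a", 0.0, 1.0), ("b", 2.0, 1.0)])
        tau2, _ = mm.eb_tau2(ests)
        assert tau2 == pytest.approx(1.0, abs=1e-6)
        assert tau2 == pytest.approx(grid_tau2_oracle([0, 2], [1, 1]), abs=1e-3)

    def test_truncated_at_zero_when_dispersion_small(self):
        tau2, _ = mm.eb_tau2(make_estimates([("a", 0.0, 1.0), ("b", 0.1, 1.0)]))
        assert tau2 == 0.0

    def test_agrees_with_grid_oracle_on_random_ensembles(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = int(rng.integers(3, 10))
            v = rng.uniform(0.02, 0.3, size=k)
            y = rng.normal(0.2, rng.uniform(0.05, 0.8), size=k)
            ests = make_estimates([(f"s{i}", y[i], v[i]) for i in range(k)])
            tau2, _ = mm.eb_tau2(ests)
            assert tau2 == pytest.approx(grid_tau2_oracle(y, v), abs=1e-3)

    def test_single_estimate_rejected(self):
        with pytest.raises(DesignError):
            mm.eb_tau2(make_estimates([("a", 0.1, 0.1)]))


class TestQStatistic:
    def test_identical_estimates_give_zero(self):
        Q, df, p = mm.q_statistic(make_estimates([("a", 0.3, 0.1), ("b", 0.3, 0.4), ("c", 0.3, 0.2)]))
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_two_study_hand_computation(self):
        Q, df, p = mm.q_statistic(make_estimates([("a", 0.0, 1.0), ("b", 2.0, 1.0)]))
        assert Q == pytest.approx(2.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.15730, abs=1e-4)


class TestPoolRandomEffects:
    def test_equal_weights_give_unweighted_mean(self):
        ests = make_estimates([("a", 0.1, 0.2), ("b", 0.4, 0.2), ("c", 0.7, 0.2)])
        m = mm.pool_random_effects(ests, tau2=0.0)
        assert m.pooled == pytest.approx(0.4, abs=1e-12)

    def test_two_study_hand_computation(self):
        m = mm.pool_random_effects(make_estimates([("a", 0.0, 1.0), ("b", 2.0, 1.0)]), tau2=0.0)
        assert m.pooled == pytest.approx(1.0, abs=1e-12)
        assert m.se == pytest.approx(0.70711, abs=1e-4)
        assert m.ci_low == pytest.approx(-0.386, abs=1e-3)
        assert m.ci_high == pytest.approx(2.386, abs=1e-3)
        assert m.p == pytest.approx(0.15730, abs=1e-4)

    def test_se_non_decreasing_in_tau2(self):
        ests = make_estimates([("a", 0.1, 0.03), ("b", 0.5, 0.2), ("c", -0.2, 0.07)])
        ses = [mm.pool_random_effects(ests, t2).se for t2 in np.linspace(0, 2, 25)]
        assert np.all(np.diff(ses) >= 0)

    def test_negative_tau2_rejected(self):
        with pytest.raises(DomainError):
            mm.pool_random_effects(make_estimates([("a", 0, 1), ("b", 1, 1)]), tau2=-0.1)


class TestAgainstMetafor:
    """Cross-check of the whole meta-analysis against an independent
    implementation (frozen metafor EB results on two fixtures)."""

    @pytest.mark.parametrize(
        "fixture,expected", [(FIXTURE_A, METAFOR_A), (FIXTURE_B, METAFOR_B)]
    )
    def test_matches_reference_implementation(self, fixture, expected):
        m = mm.random_effects_meta(make_estimates(fixture))
        for key, val in expected.items():
            assert getattr(m, key) == pytest.approx(val, abs=2e-7), key
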