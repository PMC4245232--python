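"""Mediation model fitting, posterior summaries and diagnostics."""

import numpy as np
import pytest

import medimeta as mm
from medimeta.errors import (
    ConsistencyError,
    DegenerateDataError,
    DesignError,
    DomainError,
    PrecisionError,
)
from medimeta.mediation import MediationPosterior


def _ols_paths(std):
    """Closed-form least-squares oracle for the two regressions."""
    X1 = np.column_stack([np.ones(std.n), std.T])
    X2 = np.column_stack([np.ones(std.n), std.M, std.T])
    b1 = np.linalg.solve(X1.T @ X1, X1.T @ std.M)[1]
    b3, b4 = np.linalg.solve(X2.T @ X2, X2.T @ std.Y)[1:]
    return b1, b3, b4


class TestFitMediation:
    def test_posterior_centres_on_least_squares(self, standardized_study):
        post = mm.fit_mediation(standardized_study, mm.MediationConfig(seed=3))
        b1, b3, b4 = _ols_paths(standardized_study)
        for name, ols in (("beta1", b1), ("beta3", b3), ("beta4", b4)):
            d = post.flat(name)
            mcse = d.std(ddof=1) / np.sqrt(d.size)
            assert abs(d.mean() - ols) < 4 * mcse

    def test_null_mediator_gives_null_indirect(self):
        spec = mm.spec_for_effects(0.0, 1.0)
        spec = mm.SyntheticStudySpec(
            n_control=2000, n_treated=2000, b1=spec.b1, b3=spec.b3, b4=spec.b4, seed=9
        )
        std = mm.prepare_study(mm.generate_study(spec))
        post = mm.fit_mediation(std, mm.MediationConfig(seed=4))
        assert abs(post.indirect.mean()) < 0.02

    def test_draw_count_contract(self, standardized_study):
        cfg = mm.MediationConfig(n_chains=2, n_iter=1200, seed=0)
        post = mm.fit_mediation(standardized_study, cfg)
        assert post.n_draws == 2 * 1200
        assert post.draws["beta1"].shape == (2, 1200)

    def test_gibbs_agrees_with_conjugate(self, standardized_study):
        pc = mm.fit_mediation(standardized_study, mm.MediationConfig(seed=1))
        pg = mm.fit_mediation(
            standardized_study,
            mm.MediationConfig(
                method="gibbs", n_iter=6000, burn_in=500, thin=2, seed=1
            ),
        )
        assert pg.n_draws == 3 * (6000 - 500) // 2
        for p in ("beta1", "beta3", "beta4", "sigma_m", "sigma_y"):
            assert pc.flat(p).mean() == pytest.approx(
                pg.flat(p).mean(), abs=0.05
            )

    def test_weak_prior_close_to_flat_on_standardised_data(self, standardized_study):
        pc = mm.fit_mediation(standardized_study, mm.MediationConfig(seed=2))
        pw = mm.fit_mediation(
            standardized_study,
            mm.MediationConfig(
                method="gibbs", prior="weak_normal", n_iter=6000, seed=2
            ),
        )
        assert pw.indirect.mean() == pytest.approx(pc.indirect.mean(), abs=0.05)

    def test_collinear_mediator_is_degenerate(self, toy_meta):
        T = np.array([0.0] * 5 + [1.0] * 5)
        std = mm.StandardizedStudy(T=T, M=mm.standardize(T), Y=np.linspace(-1, 1, 10), meta=toy_meta)
        with pytest.raises(DegenerateDataError):
            mm.fit_mediation(std, mm.MediationConfig(n_iter=500))

    def test_tiny_groups_rejected(self, toy_meta):
        T = np.array([0.0, 0.0, 1.0, 1.0])
        std = mm.StandardizedStudy(
            T=T, M=mm.standardize([1, 2, 3, 4]), Y=mm.standardize([2, 1, 4, 3]), meta=toy_meta
        )
        with pytest.raises(DesignError):
            mm.fit_mediation(std, mm.MediationConfig(n_iter=500))

    def test_seeded_determinism(self, standardized_study, quick_config):
        p1 = mm.fit_mediation(standardized_study, quick_config)
        p2 = mm.fit_mediation(standardized_study, quick_config)
        np.testing.assert_array_equal(p1.indirect, p2.indirect)


class TestDerivedDraws:
    def _post(self, b1, b3, b4=None):
        b1 = np.atleast_2d(np.asarray(b1, dtype=float))
        b3 = np.atleast_2d(np.asarray(b3, dtype=float))
        draws = {"beta1": b1, "beta3": b3}
        draws["beta4"] = (
            np.atleast_2d(np.asarray(b4, dtype=float))
            if b4 is not None
            else np.zeros_like(b1)
        )
        return MediationPosterior(draws=draws, study_id="t")

    @pytest.mark.parametrize(
        "b1,b3,expected",
        [
            ([1, 2], [3, 4], [3, 8]),
            ([0, 0, 0], [5, -1, 2], [0, 0, 0]),
            ([1, -1], [2, 2], [2, -2]),
        ],
    )
    def test_indirect_is_elementwise_product(self, b1, b3, expected):
        np.testing.assert_array_equal(
            mm.indirect_draws(self._post(b1, b3)), expected
        )

    def test_misaligned_draws_rejected(self):
        with pytest.raises(ConsistencyError):
            mm.indirect_draws(self._post([1, 2, 3], [1, 2]))

    def test_total_is_direct_plus_indirect_exactly(self, standardized_study, quick_config):
        post = mm.fit_mediation(standardized_study, quick_config)
        np.testing.assert_array_equal(post.total, post.indirect + post.direct)


class TestSummarizeEffect:
    def test_constant_draws(self):
        s = mm.summarize_effect(np.ones(200))
        assert (s["mean"], s["sd"], s["q2.5"], s["q97.5"]) == (1.0, 0.0, 1.0, 1.0)

    def test_normal_quantile_oracle(self):
        draws = np.random.default_rng(1).standard_normal(10**6)
        s = mm.summarize_effect(draws)
        assert s["q2.5"] == pytest.approx(-1.959964, abs=0.01)
        assert s["q97.5"] == pytest.approx(1.959964, abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(PrecisionError):
            mm.summarize_effect(np.arange(10))


class TestPercentMediated:
    def test_small_mediated_share(self):
        assert mm.percent_mediated(0.15, 1.06) == pytest.approx(12.397, abs=0.001)

    def test_moderate_mediated_share(self):
        assert mm.percent_mediated(0.399, 0.623) == pytest.approx(39.04, abs=0.01)

    def test_null_numerator(self):
        assert mm.percent_mediated(0.0, 1.0) == 0.0

    def test_zero_total_is_undefined(self):
        with pytest.raises(DomainError):
            mm.percent_mediated(0.5, -0.5)

    def test_suppression_warns(self):
        with pytest.warns(UserWarning, match="suppression"):
            mm.percent_mediated(-0.2, 1.0)


class TestGelmanRubin:
    def test_worked_two_chain_example(self):
        # W = 5/3, B = 2, n = 4  ->  sqrt((0.75*5/3 + 0.5)/(5/3))
        assert mm.gelman_rubin([[1, 2, 3, 4], [2, 3, 4, 5]]) == pytest.approx(
            1.024695, abs=1e-4
        )

    def test_identical_long_chains_near_one(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert mm.gelman_rubin([x, x]) <= 1.0 + 1e-12

    def test_single_chain_rejected(self):
        with pytest.raises(DesignError):
            mm.gelman_rubin([[1.0, 2.0, 3.0]])

    def test_zero_within_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            mm.gelman_rubin([[1.0, 1.0], [2.0, 2.0]])

    def test_well_behaved_fit_converges(self, standardized_study):
        post = mm.fit_mediation(standardized_study, mm.MediationConfig(seed=0))
        assert post.converged is True
        assert max(post.rhat.values()) <= 1.01


class TestOrientEffects:
    def test_higher_is_better_is_identity(self, standardized_study, quick_config):
        post = mm.fit_mediation(standardized_study, quick_config)
        assert mm.orient_effects(post, mm.Orientation.HIGHER_IS_BETTER) is post

    def test_lower_is_better_negates_all_effects(self, standardized_study, quick_config):
        post = mm.fit_mediation(standardized_study, quick_config)
        flipped = mm.orient_effects(post, mm.Orientation.LOWER_IS_BETTER)
        assert flipped.sign_flipped
        np.testing.assert_array_equal(flipped.indirect, -post.indirect)
        np.testing.assert_array_equal(flipped.direct, -post.direct)
        np.testing.assert_array_equal(flipped.total, -post.total)

    def test_double_application_restores(self, standardized_study, quick_config):
        post = mm.fit_mediation(standardized_study, quick_config)
        back = mm.orient_effects(
            mm.orient_effects(post, "lower_is_better"), "lower_is_better"
        )
        assert not back.sign_flipped
        np.testing.assert_array_equal(back.indirect, post.indirect)


class TestEffectEstimate:
    def test_estimate_reduces_draws(self, standardized_study, quick_config):
        post = mm.fit_mediation(standardized_study, quick_config)
        est = mm.effect_estimate(post, "indirect", outcome="task")
        d = post.indirect
        assert est.y == pytest.approx(d.mean())
        assert est.v == pytest.approx(np.var(d, ddof=1))
        assert est.ci_low <= est.y <= est.ci_high
        assert est.quantity == "indirect" and est.outcome == "task"

    def test_unknown_quantity_rejected(self, standardized_study, quick_config):
        post = mm.fit_mediation(standardized_study, quick_config)
        with pytest.raises(DomainError):
            mm.effect_estimate(post, "mystery")
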