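"""Arm contrasts, pooling arithmetic, and the stopping rule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import zitpseq as zq
from zitpseq import EffectPosterior, PosteriorDraws
from zitpseq.effects import arm_contrast, efficacy_decision, pooled_overall_effect


def _posterior(rows, covariates=("x1",), G=28):
    """PosteriorDraws from explicit coefficient rows (gamma0 last)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    from zitpseq.fit import param_names_for

    names = param_names_for(covariates, True)
    return PosteriorDraws(rows, names, np.zeros(len(rows), dtype=int),
                          "manual", tuple(covariates), True, G)


def _records(x1, arm):
    n = len(x1)
    return pd.DataFrame(
        {"id": np.arange(n), "x1": np.asarray(x1, dtype=float),
         "arm": np.asarray(arm), "outcome": np.zeros(n, dtype=int)}
    )


class TestArmContrast:
    def test_null_treatment_gives_zero(self):
        # beta0, beta_x1, beta_T, beta_inter_x1, gamma0
        post = _posterior([[2.0, 0.5, 0.0, 0.0, 0.0]] * 3)
        eff = arm_contrast(post, _records([1, 0, 1, 0], [0, 1, 0, 1]))
        assert np.allclose(eff.delta_draws, 0.0)

    def test_single_subject_single_draw(self):
        # lambda(T=1) = 15, lambda(T=0) = 13 -> delta = 2
        post = _posterior([[np.log(13.0), 0.0, np.log(15.0 / 13.0), 0.0, 0.0]])
        eff = arm_contrast(post, _records([0.0], [1]))
        assert eff.delta_draws[0] == pytest.approx(2.0, rel=1e-12)

    def test_standardization_uses_scope_covariate_mix(self):
        """Both arms must be standardized to the same biomarker mix."""
        post = _posterior([[2.0, 0.0, 0.1, 0.3, 0.0]])
        lam = lambda x, t: np.exp(2.0 + 0.1 * t + 0.3 * x * t)
        recs = _records([1, 1, 1, 0], [0, 0, 1, 1])
        expected = 0.75 * (lam(1, 1) - lam(1, 0)) + 0.25 * (lam(0, 1) - lam(0, 0))
        eff = arm_contrast(post, recs)
        assert eff.delta_draws[0] == pytest.approx(expected, rel=1e-12)

    def test_day_scale_is_bounded_by_G(self):
        post = _posterior([[np.log(40.0), 0.0, 1.0, 0.0, 0.0]], G=28)
        eff = arm_contrast(post, _records([0.0], [1]), scale="days")
        assert abs(eff.delta_draws[0]) < 28

    def test_empty_scope_errors(self):
        post = _posterior([[2.0, 0.0, 0.1, 0.0, 0.0]])
        with pytest.raises(ValueError, match="empty scope"):
            arm_contrast(post, _records([1.0], [0]), scope=np.array([False]))


class TestPooling:
    def test_equal_sizes_average(self):
        effs = [EffectPosterior(np.full(5, v)) for v in (1.0, 2.0, 3.0)]
        pooled = pooled_overall_effect(effs, [600, 600, 600])
        assert np.allclose(pooled.delta_draws, 2.0)

    def test_single_stratum_identity(self):
        e = EffectPosterior(np.array([0.3, -0.2, 1.1]))
        pooled = pooled_overall_effect([e], [17])
        assert np.allclose(pooled.delta_draws, e.delta_draws)

    def test_weight_scale_invariance(self):
        effs = [EffectPosterior(np.arange(4.0) + v) for v in (0.0, 1.0, 5.0)]
        a = pooled_overall_effect(effs, [600, 600, 600])
        b = pooled_overall_effect(effs, [2, 2, 2])
        assert np.allclose(a.delta_draws, b.delta_draws)

    def test_mismatched_draw_counts_error(self):
        with pytest.raises(ValueError, match="equal draw"):
            pooled_overall_effect(
                [EffectPosterior(np.zeros(4)), EffectPosterior(np.zeros(5))], [1, 1]
            )

    def test_pooled_between_stratum_extremes(self, rng):
        effs = [EffectPosterior(rng.normal(size=200) + mu) for mu in (0, 1, 2)]
        pooled = pooled_overall_effect(effs, [3, 5, 2])
        stacked = np.column_stack([e.delta_draws for e in effs])
        assert np.all(pooled.delta_draws >= stacked.min(axis=1) - 1e-12)
        assert np.all(pooled.delta_draws <= stacked.max(axis=1) + 1e-12)


class TestDecision:
    def test_counting(self):
        draws = np.concatenate([np.full(997, 3.0), np.full(3, 1.0)])
        rec = efficacy_decision(EffectPosterior(draws), delta=2.0, epsilon=0.995,
                                analysis_index=1, n_enrolled=500)
        assert rec.prob_exceeds_delta == pytest.approx(0.997)
        assert rec.stopped and rec.conclusion == "efficacy"

    def test_all_zero_draws_continue(self):
        rec = efficacy_decision(EffectPosterior(np.zeros(100)), 2.0, 0.995, 1, 500)
        assert rec.prob_exceeds_delta == 0.0 and not rec.stopped

    def test_boundary_is_strict(self):
        # exactly epsilon: 995 of 1000 draws above delta -> continue
        draws = np.concatenate([np.full(995, 5.0), np.full(5, 0.0)])
        rec = efficacy_decision(EffectPosterior(draws), 2.0, 0.995, 1, 500)
        assert rec.prob_exceeds_delta == pytest.approx(0.995)
        assert not rec.stopped

    def test_exceeding_delta_not_counted_at_equality(self):
        # draws exactly equal to delta must not count (strict >)
        rec = efficacy_decision(EffectPosterior(np.full(10, 2.0)), 2.0, 0.5, 1, 100)
        assert rec.prob_exceeds_delta == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        delta=st.floats(0.1, 5.0),
        shift=st.floats(0.0, 3.0),
        eps=st.floats(0.05, 0.99),
        deps=st.floats(0.0, 0.009),
    )
    def test_monotonicity(self, delta, shift, eps, deps):
        """Raising epsilon never increases stopping; raising delta never
        increases the exceedance probability."""
        draws = EffectPosterior(np.sin(np.arange(400)) * 2.0 + 2.0)
        lo = efficacy_decision(draws, delta, eps, 1, 100)
        hi_eps = efficacy_decision(draws, delta, eps + deps, 1, 100)
        hi_delta = efficacy_decision(draws, delta + shift, eps, 1, 100)
        assert hi_eps.stopped <= lo.stopped
        assert hi_delta.prob_exceeds_delta <= lo.prob_exceeds_delta


class TestSequentialTrial:
    def test_never_stops_when_epsilon_near_one(self, tiny_null_spec, tiny_settings):
        spec = dataclasses.replace(tiny_null_spec, epsilon=1.0 - 1e-12)
        res = zq.run_sequential_trial(spec, seed=1, settings=tiny_settings,
                                      compute_ranking=False)
        assert not res.stopped_early
        assert res.realized_n == spec.N_max
        assert len(res.decisions) == len(spec.looks)
        assert res.decisions[-1].conclusion in ("efficacy", "no-efficacy-at-final")

    def test_interim_stop_freezes_sample_size(self, tiny_spec, tiny_settings):
        # huge effect + permissive threshold: stops at the interim
        spec = dataclasses.replace(
            tiny_spec, epsilon=0.5,
            coef=dataclasses.replace(tiny_spec.coef, beta_T=1.0),
        )
        res = zq.run_sequential_trial(spec, seed=2, settings=tiny_settings,
                                      compute_ranking=False)
        assert res.stopped_early
        assert res.realized_n == spec.interim_sizes[0]
        assert res.efficacy

    def test_ranking_outputs_attached(self, tiny_spec, tiny_settings):
        res = zq.run_sequential_trial(tiny_spec, seed=3, settings=tiny_settings)
        assert res.marginal_rank is not None and res.joint_rank is not None
        assert sorted(res.marginal_rank.labels) == ["x1+", "x1-", "x2+", "x2-"]
        assert sorted(res.joint_rank.labels) == ["++", "+-", "-+", "--"]
        assert res.marginal_sucra.top_subgroup in res.marginal_rank.labels
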