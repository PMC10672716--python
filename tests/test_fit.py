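"""Bayesian ZITP regression: likelihood, sampler correctness, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln

import zitpseq as zq
from zitpseq import CoefficientVector, McmcSettings, PosteriorDraws
from zitpseq.fit import convergence_report, design_matrix, fit_zitp, zitp_loglik
from zitpseq._sampler import collapsed_loglik


def _df(outcomes, arms=None, x1=None, x2=None):
    n = len(outcomes)
    d = {"id": np.arange(n), "outcome": np.asarray(outcomes)}
    if arms is not None:
        d["arm"] = np.asarray(arms)
    if x1 is not None:
        d["x1"] = np.asarray(x1, dtype=float)
    if x2 is not None:
        d["x2"] = np.asarray(x2, dtype=float)
    return pd.DataFrame(d)


class TestLoglik:
    def test_single_zero_subject(self):
        # lambda = 1, phi = 0.5, G = 2 -> P(0) = 0.5 + 0.5 * 0.4 = 0.7
        coef = CoefficientVector(0.0, [], 0.0, [], 0.0)
        df = _df([0], arms=[0])
        ll = zitp_loglik(df, coef, covariate_set=(), G=2)
        assert ll == pytest.approx(math.log(0.7), abs=1e-12)

    def test_empty_records(self):
        coef = CoefficientVector(1.0, [], 0.5, [], 0.0)
        assert zitp_loglik(_df([], arms=[]), coef, covariate_set=(), G=5) == 0.0

    def test_additivity(self):
        coef = CoefficientVector(1.2, [0.3], 0.2, [-0.1], -0.4)
        one = _df([4], arms=[1], x1=[1.0])
        two = _df([4, 4], arms=[1, 1], x1=[1.0, 1.0])
        ll1 = zitp_loglik(one, coef, covariate_set=("x1",), G=10)
        ll2 = zitp_loglik(two, coef, covariate_set=("x1",), G=10)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_rejects_out_of_range_outcome(self):
        coef = CoefficientVector(1.0, [], 0.0, [], 0.0)
        with pytest.raises(ValueError):
            zitp_loglik(_df([11], arms=[0]), coef, covariate_set=(), G=10)

    def test_collapsed_loglik_matches_plain(self):
        """The sufficient-statistic collapse used inside the sampler must
        equal the per-subject likelihood up to the dropped log y! terms."""
        rng = np.random.default_rng(1)
        n, G = 60, 12
        df = _df(
            rng.integers(0, G + 1, n),
            arms=rng.integers(0, 2, n),
            x1=rng.integers(0, 2, n),
            x2=rng.integers(0, 2, n),
        )
        coef = CoefficientVector(1.4, [0.2, -0.3], 0.25, [0.1, 0.05], -0.6)
        plain = zitp_loglik(df, coef, covariate_set=("x1", "x2"), G=G)
        X, _ = design_matrix(df, ("x1", "x2"))
        from zitpseq.fit import _coef_theta, _sufficient_stats

        theta = _coef_theta(coef)
        Xp, n0, npos, S = _sufficient_stats(X, df.outcome.to_numpy())
        logfact = gammaln(np.arange(G + 1) + 1.0)
        collapsed = collapsed_loglik(Xp @ theta[:-1], expit(theta[-1]),
                                     logfact, G, n0, npos, S)
        y = df.outcome.to_numpy()
        const = gammaln(y[y > 0] + 1.0).sum()
        assert collapsed - const == pytest.approx(plain, abs=1e-8)


def _exact_posterior_moments(y, G, prior_sd):
    """2-D grid quadrature of the intercept-only ZITP posterior.

    Valid when the posterior mass is inside the grid; the test uses a
    moderately diffuse prior (sd 10) and zero-rich data so the
    phi -> 0 likelihood plateau carries negligible mass, and a grid wide
    enough to contain what remains of it.
    """
    b0 = np.linspace(-3.0, 4.5, 751)
    g0 = np.linspace(-35.0, 8.0, 1721)
    B0, G0 = np.meshgrid(b0, g0, indexing="ij")
    lam = np.exp(B0)
    phi = expit(G0)
    z = np.arange(G + 1)
    # log normalizer per grid point
    logw = B0[..., None] * z - gammaln(z + 1.0)
    m = logw.max(axis=-1, keepdims=True)
    logC = np.squeeze(m, -1) + np.log(np.exp(logw - m).sum(axis=-1))
    counts = np.bincount(y, minlength=G + 1)
    ll = np.zeros_like(B0)
    if counts[0]:
        ll += counts[0] * np.log(phi + (1 - phi) * np.exp(-logC))
    for yv in range(1, G + 1):
        if counts[yv]:
            ll += counts[yv] * (
                np.log1p(-phi) + yv * B0 - math.lgamma(yv + 1) - logC
            )
    ll += -0.5 * (B0 / prior_sd) ** 2 - 0.5 * (G0 / prior_sd) ** 2
    post = np.exp(ll - ll.max())
    post /= post.sum()
    moments = {}
    for name, grid in (("beta0", B0), ("gamma0", G0)):
        mean = (post * grid).sum()
        sd = math.sqrt((post * (grid - mean) ** 2).sum())
        moments[name] = (mean, sd)
    return moments


class TestSamplerCorrectness:
    def test_posterior_matches_quadrature_oracle(self):
        """MCMC moments on n=20, G=5, intercept-only data must match the
        exact posterior computed by deterministic 2-D quadrature."""
        G = 5
        y = zq.zitp_rng(zq.ZITPParams(3.0, 0.55, G), 20, seed=12)
        assert (y == 0).sum() >= 10  # zero-rich: phi well identified
        prior = zq.PriorSpec(mean=0.0, sd=10.0)
        exact = _exact_posterior_moments(y, G, prior.sd)
        draws = fit_zitp(
            _df(y), covariate_set=(), include_treatment=False, G=G, prior=prior,
            settings=McmcSettings(chains=3, burn_in=2000, keep=8000, seed=5),
        )
        report = convergence_report(draws)
        for name in ("beta0", "gamma0"):
            mean_exact, sd_exact = exact[name]
            mcse = draws.sd()[name] / math.sqrt(report.loc[name, "ess_bulk"])
            assert abs(draws.mean()[name] - mean_exact) < 3 * mcse
            assert draws.sd()[name] == pytest.approx(sd_exact, rel=0.12)

    def test_reproducible_under_seed(self, scenario1_cohort):
        settings = McmcSettings(chains=2, burn_in=300, keep=500, seed=3)
        a = fit_zitp(scenario1_cohort.head(300), covariate_set=("x1",), settings=settings)
        b = fit_zitp(scenario1_cohort.head(300), covariate_set=("x1",), settings=settings)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_dominance_on_empty_data(self):
        """With no likelihood the posterior must reproduce the prior."""
        with pytest.warns(UserWarning, match="no data"):
            draws = fit_zitp(
                _df([]), covariate_set=(), include_treatment=False,
                settings=McmcSettings(chains=2, burn_in=5000, keep=5000, seed=8),
            )
        for name in ("beta0", "gamma0"):
            assert 0.6e4 < draws.sd()[name] < 1.4e4

    def test_no_inflation_pushes_gamma0_negative(self):
        spec = zq.scenario_spec(1, phi=0.0)
        # rebuild coefficients with a very negative gamma0 (phi ~ 0)
        import dataclasses

        coef = dataclasses.replace(spec.coef, gamma0=-30.0)
        spec = dataclasses.replace(spec, coef=coef)
        df = zq.generate_cohort(spec, 1200, seed=21)
        draws = fit_zitp(df, covariate_set=("x1", "x2"),
                         settings=McmcSettings(chains=2, burn_in=800, keep=1500, seed=9))
        assert np.quantile(draws["gamma0"], 0.95) < math.log(0.02 / 0.98)


class TestGuards:
    def test_refuses_fewer_subjects_than_parameters(self):
        df = _df([1, 2, 3], arms=[0, 1, 0], x1=[1, 0, 1], x2=[0, 1, 1])
        with pytest.raises(ValueError, match="refusing"):
            fit_zitp(df, covariate_set=("x1", "x2"))

    def test_requires_two_subjects_per_arm(self):
        df = _df([1, 2, 3, 4, 5, 6], arms=[1, 1, 1, 1, 1, 0],
                 x1=[1, 0, 1, 0, 1, 0])
        with pytest.raises(ValueError, match="per arm"):
            fit_zitp(df, covariate_set=("x1",))

    def test_warns_on_all_zero_arm(self, tiny_settings):
        rng = np.random.default_rng(13)
        n = 40
        df = _df(
            np.where(rng.integers(0, 2, n) == 1, rng.integers(1, 9, n), 0),
            arms=rng.integers(0, 2, n),
        )
        df.loc[df.arm == 1, "outcome"] = 0
        with pytest.warns(UserWarning, match="zero"):
            fit_zitp(df, covariate_set=(), settings=tiny_settings)


class TestDiagnostics:
    def test_well_mixed_fit_has_small_rhat(self, scenario1_cohort, reduced_settings):
        cc = scenario1_cohort[scenario1_cohort[["x1", "x2"]].notna().all(axis=1)]
        draws = fit_zitp(cc, covariate_set=("x1", "x2"), settings=reduced_settings)
        report = convergence_report(draws)
        assert (report["rhat"] < 1.05).all()

    def test_identical_chains_rhat_one(self, rng):
        base = rng.normal(size=(2000, 2))
        draws = np.vstack([base, base, base])
        chain = np.repeat([0, 1, 2], len(base))
        pdr = PosteriorDraws(draws, ["beta0", "gamma0"], chain, "toy", (), False, 28)
        report = convergence_report(pdr)
        assert np.allclose(report["rhat"], 1.0, atol=0.01)

    def test_white_noise_ess_near_total(self, rng):
        draws = rng.normal(size=(6000, 1))
        chain = np.repeat([0, 1, 2], 2000)
        pdr = PosteriorDraws(draws, ["beta0"], chain, "toy", (), False, 28)
        report = convergence_report(pdr)
        assert report["ess_bulk"].iloc[0] > 3000

    def test_single_chain_omits_rhat(self, rng):
        draws = rng.normal(size=(500, 1))
        pdr = PosteriorDraws(draws, ["beta0"], np.zeros(500, dtype=int), "toy", (), False, 28)
        report = convergence_report(pdr)
        assert report["rhat"].isna().all()
        assert "note" in report.attrs


def test_posterior_csv_roundtrip(tmp_path, scenario1_cohort, tiny_settings):
    draws = fit_zitp(scenario1_cohort.head(400), covariate_set=("x1",),
                     settings=tiny_settings)
    path = tmp_path / "draws.csv"
    draws.to_csv(path)
    back = PosteriorDraws.from_csv(path, covariates=("x1",))
    assert back.param_names == draws.param_names
    assert np.allclose(back.draws, draws.draws)
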