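"""Bayesian estimation of the ZITP regression by MCMC.

The model for a covariate set C (a subset of the biomarkers) is

    log(lambda_i) = beta0 + sum_{j in C} beta_xj x_ji + beta_T T_i
                  + sum_{j in C} beta_inter_j x_ji T_i
    logit(phi)    = gamma0

with independent normal priors (default mean 0, sd 1e4) on every
coefficient and on gamma0.  Posterior draws come from an adaptive
random-walk Metropolis-within-Gibbs sampler (see ``_sampler``); any
subject whose covariate-set biomarkers are missing is excluded
(complete-case fitting).

Default chain settings are three chains with a 10,000-draw burn-in and
30,000 kept draws each; :meth:`McmcSettings.reduced` gives the
desk-scale 3 x (1,000 + 3,000) configuration used throughout the test
suite and the shipped replication studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._sampler import run_chain
from .zitp import CoefficientVector, ZITPParams, zitp_logpmf
from .cohort import biomarker_columns

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "PosteriorDraws",
    "design_matrix",
    "zitp_loglik",
    "fit_zitp",
    "convergence_report",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal prior applied to every coefficient and gamma0."""

    mean: float = 0.0
    sd: float = 1.0e4

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError("prior sd must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Chain configuration.  ``keep`` counts kept draws per chain."""

    chains: int = 3
    burn_in: int = 10_000
    keep: int = 30_000
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 1 or self.burn_in < 0 or self.keep < 1 or self.thin < 1:
            raise ValueError("invalid MCMC settings")

    @classmethod
    def reduced(cls, seed: int | None = None, **kw) -> "McmcSettings":
        """Desk-scale settings: 3 chains x (1,000 burn + 3,000 keep)."""
        return cls(chains=3, burn_in=1_000, keep=3_000, seed=seed, **kw)

    def with_seed(self, seed) -> "McmcSettings":
        return replace(self, seed=seed)


@dataclass
class PosteriorDraws:
    """Matrix of kept MCMC draws.

    ``draws`` has one row per kept draw (chains stacked) and one column
    per parameter in ``param_names`` order: beta0, biomarker main
    effects, beta_T (if the model has a treatment term), interactions,
    gamma0 last.
    """

    draws: np.ndarray
    param_names: list[str]
    chain_id: np.ndarray
    model_tag: str
    covariates: tuple[str, ...]
    include_treatment: bool
    G: int
    accept_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("posterior draws contain non-finite values")
        if self.draws.shape[1] != len(self.param_names):
            raise ValueError("parameter count mismatch")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_chains(self) -> int:
        return int(np.unique(self.chain_id).size)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    @property
    def beta(self) -> np.ndarray:
        """Regression-coefficient draws (everything except gamma0)."""
        return self.draws[:, :-1]

    @property
    def gamma0(self) -> np.ndarray:
        return self.draws[:, -1]

    @property
    def phi(self) -> np.ndarray:
        return expit(self.gamma0)

    def mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=self.param_names)

    def sd(self) -> pd.Series:
        return pd.Series(self.draws.std(axis=0, ddof=1), index=self.param_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.param_names)
        df.insert(0, "chain", self.chain_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_tag="from-csv", covariates=(),
                 include_treatment=True, G=28) -> "PosteriorDraws":
        df = pd.read_csv(path)
        chain = df.pop("chain").to_numpy()
        return cls(df.to_numpy(float), list(df.columns), chain, model_tag,
                   tuple(covariates), include_treatment, G)

    def to_arviz(self) -> az.InferenceData:
        chains = np.unique(self.chain_id)
        per = [self.draws[self.chain_id == c] for c in chains]
        k = min(len(a) for a in per)
        stacked = np.stack([a[:k] for a in per])  # (chain, draw, param)
        return az.from_dict(
            posterior={name: stacked[:, :, i] for i, name in enumerate(self.param_names)}
        )


def param_names_for(covariates, include_treatment: bool = True) -> list[str]:
    names = ["beta0"] + [f"beta_{c}" for c in covariates]
    if include_treatment:
        names += ["beta_T"] + [f"beta_inter_{c}" for c in covariates]
    return names + ["gamma0"]


def design_matrix(records: pd.DataFrame, covariates,
                  include_treatment: bool = True,
                  treatment=None) -> tuple[np.ndarray, list[str]]:
    """Regression design: intercept, biomarkers, treatment, interactions.

    ``treatment`` overrides the ``arm`` column (scalar or vector), which
    is how marginal standardization forces T = 1 / T = 0.
    """
    covariates = tuple(covariates)
    n = len(records)
    x = records[list(covariates)].to_numpy(dtype=float) if covariates else np.zeros((n, 0))
    cols = [np.ones(n)] + [x[:, j] for j in range(len(covariates))]
    if include_treatment:
        if treatment is None:
            t = records["arm"].to_numpy(dtype=float)
        else:
            t = np.broadcast_to(np.asarray(treatment, dtype=float), (n,))
        cols += [t] + [x[:, j] * t for j in range(len(covariates))]
    X = np.column_stack(cols) if n else np.zeros((0, len(cols)))
    names = param_names_for(covariates, include_treatment)
    return X, names[:-1]


def _coef_theta(coef: CoefficientVector, include_treatment: bool = True) -> np.ndarray:
    parts = [[coef.beta0], coef.beta_x]
    if include_treatment:
        parts += [[coef.beta_T], coef.beta_inter]
    parts += [[coef.gamma0]]
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def zitp_loglik(records: pd.DataFrame, coef: CoefficientVector,
                covariate_set=None, G: int = 28,
                include_treatment: bool = True) -> float:
    """Exact log likelihood of a cohort under given coefficients.

    ``covariate_set`` restricts the linear predictor to those biomarker
    columns (``coef`` must match its size); records must all have
    observed outcomes in [0, G].
    """
    if len(records) == 0:
        return 0.0
    covariates = tuple(covariate_set) if covariate_set is not None \
        else tuple(biomarker_columns(records))
    y = records["outcome"].to_numpy()
    if np.any(pd.isna(y)) or np.any((y < 0) | (y > G)):
        raise ValueError(f"outcomes must be observed and lie in [0, {G}]")
    X, _ = design_matrix(records, covariates, include_treatment)
    if np.any(np.isnan(X)):
        raise ValueError("covariate-set biomarkers must be non-missing")
    theta = _coef_theta(coef, include_treatment)
    eta = X @ theta[:-1]
    phi = float(expit(theta[-1]))
    ll = 0.0
    for lam_i, y_i in zip(np.exp(eta), y):
        ll += float(zitp_logpmf(int(y_i), ZITPParams(lam_i, phi, G)))
    return ll


def _sufficient_stats(X: np.ndarray, y: np.ndarray):
    """Collapse subjects to unique design rows with (n0, npos, S)."""
    if len(X) == 0:
        return X.reshape(0, X.shape[1]), np.zeros(0), np.zeros(0), np.zeros(0)
    uniq, inv = np.unique(X, axis=0, return_inverse=True)
    P = len(uniq)
    zero = y == 0
    n0 = np.bincount(inv[zero], minlength=P).astype(float)
    npos = np.bincount(inv[~zero], minlength=P).astype(float)
    S = np.bincount(inv[~zero], weights=y[~zero].astype(float), minlength=P)
    return uniq, n0, npos, S


def _initial_values(y: np.ndarray, p: int) -> np.ndarray:
    init = np.zeros(p + 1)
    if len(y):
        pos = y[y > 0]
        init[0] = np.log(pos.mean()) if len(pos) else 0.0
        zf = np.clip((y == 0).mean(), 0.02, 0.98)
        init[p] = np.log(zf / (1 - zf))
    return init


def fit_zitp(records: pd.DataFrame, covariate_set=None,
             prior: PriorSpec | None = None,
             settings: McmcSettings | None = None,
             G: int = 28, include_treatment: bool = True,
             model_tag: str | None = None) -> PosteriorDraws:
    """Fit the ZITP regression by MCMC and return posterior draws.

    Records with missing covariate-set biomarkers are dropped
    (complete-case analysis).  An empty record set is allowed and samples
    the prior; otherwise the fit refuses when there are fewer subjects
    than parameters, or fewer than two subjects in either arm of a
    treatment model.
    """
    prior = prior or PriorSpec()
    settings = settings or McmcSettings()
    covariates = tuple(covariate_set) if covariate_set is not None \
        else tuple(biomarker_columns(records))
    tag = model_tag or ("+".join(covariates) if covariates else "intercept")

    sub = records
    if covariates:
        sub = records.loc[records[list(covariates)].notna().all(axis=1)]
    n = len(sub)
    names = param_names_for(covariates, include_treatment)
    d = len(names)

    if n == 0:
        warnings.warn("fitting with no data: posterior equals the prior")
        X = np.zeros((0, d - 1))
        y = np.zeros(0, dtype=np.int64)
    else:
        y = sub["outcome"].to_numpy()
        if np.any(pd.isna(y)) or np.any((y < 0) | (y > G)):
            raise ValueError(f"outcomes must be observed and lie in [0, {G}]")
        y = y.astype(np.int64)
        if n < d:
            raise ValueError(f"{n} subjects cannot identify {d} parameters; refusing to fit")
        if include_treatment:
            arms = sub["arm"].to_numpy()
            if (arms == 1).sum() < 2 or (arms == 0).sum() < 2:
                raise ValueError("need at least two subjects per arm")
            for a in (0, 1):
                ya = y[arms == a]
                if len(ya) and np.all(ya == 0):
                    warnings.warn(f"all outcomes are zero in arm {a}; "
                                  "fit proceeds under the priors")
        X, _ = design_matrix(sub, covariates, include_treatment)

    Xp, n0, npos, S = _sufficient_stats(X, y)
    logfact = gammaln(np.arange(G + 1) + 1.0)
    prior_mean = np.full(d, prior.mean)
    prior_sd = np.full(d, prior.sd)
    init = _initial_values(y, d - 1)

    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = ss.generate_state(settings.chains).astype(np.int64) % (2**31)
    all_draws, all_chain, all_acc = [], [], []
    for c in range(settings.chains):
        draws, acc = run_chain(
            np.ascontiguousarray(Xp, dtype=np.float64), n0, npos, S,
            int(G), logfact, prior_mean, prior_sd, init,
            settings.burn_in, settings.keep, settings.thin,
            int(chain_seeds[c]), 0.1,
        )
        all_draws.append(draws)
        all_chain.append(np.full(len(draws), c, dtype=np.int64))
        all_acc.append(acc)
    return PosteriorDraws(
        draws=np.vstack(all_draws),
        param_names=names,
        chain_id=np.concatenate(all_chain),
        model_tag=tag,
        covariates=covariates,
        include_treatment=include_treatment,
        G=int(G),
        accept_rates=np.mean(all_acc, axis=0),
    )


def convergence_report(pd_draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter split-R-hat and effective sample size.

    With a single chain, R-hat cannot be computed and the column is NaN
    (noted in ``DataFrame.attrs['note']``).
    """
    idata = pd_draws.to_arviz()
    ess = az.ess(idata)
    report = pd.DataFrame(index=pd.Index(pd_draws.param_names, name="parameter"))
    report["ess_bulk"] = [float(ess[p].values) for p in pd_draws.param_names]
    if pd_draws.n_chains >= 2:
        rhat = az.rhat(idata)
        report["rhat"] = [float(rhat[p].values) for p in pd_draws.param_names]
    else:
        report["rhat"] = np.nan
        report.attrs["note"] = "single chain: R-hat omitted"
    return report
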