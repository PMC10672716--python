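"""Arm-level treatment contrasts, pooling, and the sequential stopping rule.

The efficacy estimand is the lambda-scale contrast
``lambda_{T=1} - lambda_{T=0}`` (extra event-free days implied by the
count process).  Subject-level lambdas are turned into arm-level ones by
marginal standardization: for each posterior draw, every in-scope
subject's lambda is computed twice — forcing T = 1 and T = 0 — and
averaged over subjects, so both arms are standardized to the same
covariate mix.  A day-scale contrast on the expected outcome
``(1 - phi) * truncated mean`` is available as a secondary scale.

The trial stops early for efficacy (and only for efficacy) under the
Thall–Simon rule: stop iff ``Pr(lambda_1 - lambda_0 > delta | data)``
strictly exceeds epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .fit import McmcSettings, PosteriorDraws, PriorSpec, fit_zitp
from .scenarios import ScenarioSpec

__all__ = [
    "EffectPosterior",
    "DecisionRecord",
    "TrialResult",
    "analysis_sets",
    "arm_contrast",
    "pooled_overall_effect",
    "efficacy_decision",
    "run_sequential_trial",
]


@dataclass
class EffectPosterior:
    """Posterior draws of a treatment contrast (days, experimental - control)."""

    delta_draws: np.ndarray
    scope: str = "overall"

    def __post_init__(self) -> None:
        self.delta_draws = np.asarray(self.delta_draws, dtype=float)
        if self.delta_draws.ndim != 1 or self.delta_draws.size == 0:
            raise ValueError("delta_draws must be a nonempty 1-D vector")

    @property
    def n_draws(self) -> int:
        return self.delta_draws.size


@dataclass(frozen=True)
class DecisionRecord:
    """Outcome of applying the stopping rule at one analysis."""

    analysis_index: int
    n_enrolled: int
    prob_exceeds_delta: float
    stopped: bool
    conclusion: str  # "efficacy" | "continue" | "no-efficacy-at-final"


def _pattern_weights(records: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray]:
    x = records[list(covariates)].to_numpy(dtype=float) if covariates else \
        np.zeros((len(records), 0))
    if np.any(np.isnan(x)):
        raise ValueError("scope must contain only the fitted model's complete cases")
    uniq, counts = np.unique(x, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def _design_rows(patterns: np.ndarray, t: float, include_treatment: bool) -> np.ndarray:
    U, m = patterns.shape
    cols = [np.ones(U)] + [patterns[:, j] for j in range(m)]
    if include_treatment:
        cols += [np.full(U, t)] + [patterns[:, j] * t for j in range(m)]
    return np.column_stack(cols)


def _truncated_mean(lam: np.ndarray, G: int) -> np.ndarray:
    """Mean of the truncated Poisson, vectorized over a lambda array."""
    z = np.arange(G + 1, dtype=float)
    logw = np.log(lam)[..., None] * z - gammaln(z + 1)
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    return (w * z).sum(axis=-1) / w.sum(axis=-1)


def arm_contrast(posterior: PosteriorDraws, records: pd.DataFrame,
                 scope=None, scope_label: str = "overall",
                 scale: str = "lambda",
                 pattern: np.ndarray | None = None) -> EffectPosterior:
    """Marginally standardized treatment contrast for a subject scope.

    ``scope`` selects rows of ``records`` (boolean mask or id array);
    alternatively ``pattern`` gives a single covariate pattern directly
    (model-based contrast, used when a subgroup cell is empty).
    ``scale`` is "lambda" (count-process mean, the decision scale) or
    "days" (expected outcome ``(1 - phi) * truncated mean``).
    """
    if not posterior.include_treatment:
        raise ValueError("posterior has no treatment term")
    if pattern is not None:
        patterns = np.atleast_2d(np.asarray(pattern, dtype=float))
        weights = np.ones(len(patterns))
    else:
        sub = records
        if scope is not None:
            scope = np.asarray(scope)
            if scope.dtype == bool:
                sub = records.loc[scope]
            else:
                sub = records.loc[records["id"].isin(scope)]
        if len(sub) == 0:
            raise ValueError(f"empty scope {scope_label!r}")
        patterns, weights = _pattern_weights(sub, posterior.covariates)
    weights = weights / weights.sum()
    B = posterior.beta  # (D, p)
    lam = {}
    with np.errstate(over="ignore"):
        for t in (1.0, 0.0):
            Xd = _design_rows(patterns, t, include_treatment=True)
            lam[t] = np.exp(B @ Xd.T)  # (D, U)
    if scale == "lambda":
        val1, val0 = lam[1.0], lam[0.0]
    elif scale == "days":
        keep = (1.0 - expit(posterior.gamma0))[:, None]
        val1 = keep * _truncated_mean(lam[1.0], posterior.G)
        val0 = keep * _truncated_mean(lam[0.0], posterior.G)
    else:
        raise ValueError("scale must be 'lambda' or 'days'")
    # draws extreme enough to overflow exp() yield non-finite contrasts;
    # downstream they never count as exceeding delta (conservative)
    with np.errstate(invalid="ignore"):
        delta = (val1 - val0) @ weights
    return EffectPosterior(delta, scope=scope_label)


def pooled_overall_effect(stratum_effects: list[EffectPosterior],
                          stratum_sizes) -> EffectPosterior:
    """Draw-wise weighted average of stratum effects, weights ~ sizes."""
    sizes = np.asarray(stratum_sizes, dtype=float)
    if len(stratum_effects) != sizes.size or sizes.size == 0:
        raise ValueError("one size per stratum effect required")
    lengths = {e.n_draws for e in stratum_effects}
    if len(lengths) != 1:
        raise ValueError("stratum effects must have equal draw counts")
    if sizes.sum() <= 0:
        raise ValueError("stratum sizes must be positive in total")
    w = sizes / sizes.sum()
    pooled = sum(wi * e.delta_draws for wi, e in zip(w, stratum_effects))
    return EffectPosterior(pooled, scope="overall")


def efficacy_decision(effect: EffectPosterior, delta: float, epsilon: float,
                      analysis_index: int, n_enrolled: int,
                      final: bool = False) -> DecisionRecord:
    """Apply the posterior-probability superiority rule at one look.

    ``prob_exceeds_delta`` is the fraction of draws strictly greater than
    delta; the trial stops iff it strictly exceeds epsilon.
    """
    prob = float(np.mean(effect.delta_draws > delta))
    exceeds = prob > epsilon
    if exceeds:
        conclusion = "efficacy"
    else:
        conclusion = "no-efficacy-at-final" if final else "continue"
    return DecisionRecord(
        analysis_index=analysis_index,
        n_enrolled=int(n_enrolled),
        prob_exceeds_delta=prob,
        stopped=bool(exceeds and not final),
        conclusion=conclusion,
    )


def analysis_sets(records: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """The missingness-defined analysis cases pooled at each look.

    One case per fitted covariate set: the all-biomarker model on
    complete cases ("both" for m = 2), plus one single-biomarker model
    per biomarker on every patient with that biomarker measured
    ("x1-only" = the x1-only *model*; its analysis set overlaps the
    complete cases).  Values are the covariate tuples; the fit itself
    restricts to that set's complete cases.
    """
    from .cohort import biomarker_columns

    cols = tuple(biomarker_columns(records))
    key_all = "both" if len(cols) == 2 else "all"
    out = {key_all: cols}
    for c in cols:
        out[f"{c}-only"] = (c,)
    return out


@dataclass
class TrialResult:
    """One simulated trial: per-look decisions plus stopping-time ranking."""

    decisions: list[DecisionRecord]
    realized_n: int
    stopped_early: bool
    efficacy: bool
    marginal_rank: "object | None" = None   # RankMatrix
    marginal_sucra: "object | None" = None  # SucraSummary
    joint_rank: "object | None" = None
    joint_sucra: "object | None" = None
    seed: object = None

    @property
    def final_decision(self) -> DecisionRecord:
        return self.decisions[-1]


def run_sequential_trial(spec: ScenarioSpec, seed=None,
                         settings: McmcSettings | None = None,
                         prior: PriorSpec | None = None,
                         compute_ranking: bool = True) -> TrialResult:
    """Simulate one group-sequential trial under a scenario.

    The full cohort of ``N_max`` patients is generated up front and
    revealed in enrollment order.  At each look three models are fitted
    on the accumulated data — the two-biomarker model on complete cases
    and each single-biomarker model on every patient with that biomarker
    measured — their marginally standardized contrasts are pooled with
    weights equal to the observed analysis-set sizes, and the efficacy
    rule is applied; the trial stops at the first interim exceedance,
    else runs to the final analysis at ``N_max``.  At the stopping
    analysis the subgroups are ranked by SUCRA in the marginal
    configuration (from the two single-biomarker fits) and the
    complete-case joint configuration (from the two-biomarker fit).
    """
    from .cohort import generate_cohort
    from . import ranking

    settings = settings or McmcSettings.reduced()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cohort, s_mcmc, s_ties = ss.spawn(3)
    cohort = generate_cohort(spec, spec.N_max, s_cohort)

    def _fit_seed(child: np.random.SeedSequence) -> int:
        return int(child.generate_state(1)[0] % (2**31))

    fit_stream = iter(s_mcmc.spawn((spec.m + 1) * len(spec.looks)))

    decisions: list[DecisionRecord] = []
    stop_data: pd.DataFrame | None = None
    stop_fits: dict[str, PosteriorDraws] = {}
    stopped_early = False
    realized_n = spec.N_max
    for k, n_k in enumerate(spec.looks, start=1):
        final = n_k == spec.N_max
        data_k = cohort.iloc[:n_k]
        effects, sizes, fits = [], [], {}
        for key, covs in analysis_sets(data_k).items():
            members = data_k.loc[data_k[list(covs)].notna().all(axis=1)]
            pdraws = fit_zitp(
                members, covariate_set=covs, prior=prior,
                settings=settings.with_seed(_fit_seed(next(fit_stream))),
                G=spec.G, model_tag=key,
            )
            fits[key] = pdraws
            effects.append(arm_contrast(pdraws, members, scope_label=key))
            sizes.append(len(members))
        pooled = pooled_overall_effect(effects, sizes)
        decision = efficacy_decision(pooled, spec.delta, spec.epsilon,
                                     analysis_index=k, n_enrolled=n_k, final=final)
        decisions.append(decision)
        if decision.stopped or final:
            stopped_early = decision.stopped
            realized_n = n_k
            stop_data = data_k
            stop_fits = fits
            break

    result = TrialResult(
        decisions=decisions,
        realized_n=realized_n,
        stopped_early=stopped_early,
        efficacy=decisions[-1].conclusion == "efficacy",
        seed=ss.entropy,
    )

    if compute_ranking and stop_data is not None and spec.m == 2:
        tie_rng = np.random.default_rng(s_ties)
        marg = ranking.marginal_subgroup_effects(
            stop_fits["x1-only"], stop_fits["x2-only"], stop_data)
        result.marginal_rank = ranking.rank_distribution(marg, rng=tie_rng)
        result.marginal_sucra = ranking.sucra(result.marginal_rank)
        both_key = "both" if "both" in stop_fits else "all"
        if both_key in stop_fits:
            joint = ranking.joint_subgroup_effects(stop_fits[both_key], stop_data)
            result.joint_rank = ranking.rank_distribution(joint, rng=tie_rng)
            result.joint_sucra = ranking.sucra(result.joint_rank)
    return result
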