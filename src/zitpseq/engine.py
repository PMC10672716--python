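"""Replication driver and operating-characteristics calculator.

Runs many independent simulated trials per configuration and aggregates
their decisions into design operating characteristics: positive rate
(fraction of replications concluding efficacy — the false-positive rate
under the null scenario, the true-positive rate otherwise), early
stopping rate, average realized sample size, correct-identification
rate of the most predictive subgroup, and averaged rank-probability
matrices.  Every rate carries a binomial Monte-Carlo standard error.

Seeding is hierarchical: a master seed spawns one independent substream
per replication, which in turn feeds the cohort, each MCMC fit, and the
rank tie-breaks.  Results are therefore identical for any worker count
and any single replication can be replayed from its recorded seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import generate_biomarkers  # noqa: F401  (re-export convenience)
from .effects import TrialResult, run_sequential_trial
from .fit import McmcSettings, PriorSpec
from .ranking import RankMatrix
from .scenarios import ScenarioSpec, scenario_spec
from .zitp import linear_predictor

__all__ = [
    "OperatingCharacteristics",
    "true_marginal_contrasts",
    "true_best_marginal_subgroup",
    "replicate_study",
    "sensitivity_sweep",
    "write_report",
]


@dataclass
class OperatingCharacteristics:
    """Aggregated design behavior over replications of one configuration."""

    scenario: str
    prevalence_x2: float
    n_reps: int
    positive_rate: float
    early_stopping_rate: float
    average_sample_size: float
    correct_identification_rate: float  # NaN when the truth is a tie (null)
    positive_rate_se: float
    early_stopping_rate_se: float
    rank_probability_means: dict = field(default_factory=dict)
    master_seed: object = None
    replications: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in (self.positive_rate, self.early_stopping_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "prevalence_x2": self.prevalence_x2,
            "n_reps": self.n_reps,
            "average_sample_size": self.average_sample_size,
            "positive_rate": self.positive_rate,
            "early_stopping_rate": self.early_stopping_rate,
            "correct_identification_rate": self.correct_identification_rate,
            "positive_rate_se": self.positive_rate_se,
            "early_stopping_rate_se": self.early_stopping_rate_se,
        }


def true_marginal_contrasts(spec: ScenarioSpec) -> dict[str, float]:
    """Closed-form lambda-scale contrast of each marginal subgroup.

    For subgroup xj = v, membership mixes equally over the "both
    measured" and "only xj measured" terciles, and within "both" over
    the other biomarker's prevalence.  Missing biomarkers contribute
    zero to the generative linear predictor, matching data generation.
    """
    if spec.m != 2:
        raise ValueError("marginal-subgroup truth is defined for m = 2")
    out: dict[str, float] = {}
    for j in range(2):
        other = 1 - j
        p_other = spec.prevalence[other]
        for v, sign in ((1.0, "+"), (0.0, "-")):
            contrast = 0.0
            # stratum "both measured" (weight 1/2), other biomarker mixed
            for o_val, o_w in ((1.0, p_other), (0.0, 1.0 - p_other)):
                prof = np.empty(2)
                prof[j], prof[other] = v, o_val
                contrast += 0.5 * o_w * (
                    linear_predictor(spec.coef, prof, 1)
                    - linear_predictor(spec.coef, prof, 0)
                )
            # stratum "only xj measured" (weight 1/2), other set missing
            prof = np.full(2, np.nan)
            prof[j] = v
            contrast += 0.5 * (
                linear_predictor(spec.coef, prof, 1)
                - linear_predictor(spec.coef, prof, 0)
            )
            out[f"x{j + 1}{sign}"] = float(contrast)
    return out


def true_best_marginal_subgroup(spec: ScenarioSpec, tol: float = 1e-9) -> str | None:
    """Label of the subgroup with the largest true contrast; None on ties."""
    contrasts = true_marginal_contrasts(spec)
    ordered = sorted(contrasts.items(), key=lambda kv: -kv[1])
    if ordered[0][1] - ordered[1][1] <= tol:
        return None
    return ordered[0][0]


def _one_replication(spec: ScenarioSpec, rep: int, master_seed: int,
                     settings: McmcSettings, prior, compute_ranking: bool):
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(rep,))
    return run_sequential_trial(spec, seed=ss, settings=settings, prior=prior,
                                compute_ranking=compute_ranking)


def _mean_rank_matrix(matrices: list[RankMatrix]) -> RankMatrix | None:
    matrices = [m for m in matrices if m is not None]
    if not matrices:
        return None
    probs = np.mean([m.probs for m in matrices], axis=0)
    return RankMatrix(probs, matrices[0].labels)


def replicate_study(spec: ScenarioSpec, n_reps: int, master_seed: int = 0,
                    settings: McmcSettings | None = None,
                    prior: PriorSpec | None = None,
                    workers: int = 1,
                    compute_ranking: bool = True) -> OperatingCharacteristics:
    """Operating characteristics over ``n_reps`` independent trials.

    Per-replication seeds derive deterministically from ``master_seed``,
    so the result is invariant to ``workers``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    settings = settings or McmcSettings.reduced()
    if workers > 1:
        results: list[TrialResult] = Parallel(n_jobs=workers)(
            delayed(_one_replication)(spec, rep, master_seed, settings, prior,
                                      compute_ranking)
            for rep in range(n_reps)
        )
    else:
        results = [
            _one_replication(spec, rep, master_seed, settings, prior, compute_ranking)
            for rep in range(n_reps)
        ]

    positives = np.array([r.efficacy for r in results], dtype=float)
    early = np.array([r.stopped_early for r in results], dtype=float)
    sizes = np.array([r.realized_n for r in results], dtype=float)

    truth = true_best_marginal_subgroup(spec)
    if truth is None or not compute_ranking:
        correct = float("nan")
    else:
        hits = [r.marginal_sucra.top_subgroup == truth
                for r in results if r.marginal_sucra is not None]
        correct = float(np.mean(hits)) if hits else float("nan")

    rank_means: dict[str, RankMatrix] = {}
    if compute_ranking:
        marg = _mean_rank_matrix([r.marginal_rank for r in results])
        joint = _mean_rank_matrix([r.joint_rank for r in results])
        if marg is not None:
            rank_means["marginal"] = marg
        if joint is not None:
            rank_means["joint"] = joint

    def _se(p: float) -> float:
        return float(np.sqrt(p * (1.0 - p) / n_reps))

    reps_summary = [
        {
            "rep": i,
            "efficacy": bool(r.efficacy),
            "stopped_early": bool(r.stopped_early),
            "realized_n": int(r.realized_n),
            "prob_trace": [d.prob_exceeds_delta for d in r.decisions],
            "top_subgroup": (r.marginal_sucra.top_subgroup
                             if r.marginal_sucra is not None else None),
        }
        for i, r in enumerate(results)
    ]

    return OperatingCharacteristics(
        scenario=spec.name,
        prevalence_x2=float(spec.prevalence[-1]),
        n_reps=n_reps,
        positive_rate=float(positives.mean()),
        early_stopping_rate=float(early.mean()),
        average_sample_size=float(sizes.mean()),
        correct_identification_rate=correct,
        positive_rate_se=_se(float(positives.mean())),
        early_stopping_rate_se=_se(float(early.mean())),
        rank_probability_means=rank_means,
        master_seed=master_seed,
        replications=reps_summary,
    )


def sensitivity_sweep(base_spec: ScenarioSpec, prevalences, n_reps: int,
                      master_seed: int = 0,
                      settings: McmcSettings | None = None,
                      workers: int = 1,
                      compute_ranking: bool = True) -> list[OperatingCharacteristics]:
    """One replication study per x2 prevalence, all else fixed."""
    from dataclasses import replace

    out = []
    for i, prev in enumerate(prevalences):
        spec = replace(base_spec,
                       prevalence=np.array([base_spec.prevalence[0], float(prev)]))
        out.append(replicate_study(spec, n_reps,
                                   master_seed=master_seed + i,
                                   settings=settings, workers=workers,
                                   compute_ranking=compute_ranking))
    return out


def write_report(results: list[OperatingCharacteristics], path_prefix) -> dict:
    """Emit the operating-characteristics table (CSV) and the full JSON.

    Returns the paths written.  The CSV has one row per (scenario,
    prevalence) configuration; the JSON additionally carries averaged
    rank matrices, per-replication records, and the master seeds needed
    for replay.  Rank-matrix columns are omitted entirely when ranking
    was disabled.
    """
    if not results:
        raise ValueError("no results to report")
    import pathlib

    prefix = pathlib.Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")

    pd.DataFrame([r.to_row() for r in results]).to_csv(csv_path, index=False)

    payload = []
    for r in results:
        entry = r.to_row()
        entry["master_seed"] = r.master_seed
        entry["replications"] = r.replications
        if r.rank_probability_means:
            entry["rank_probability_means"] = {
                cfg: {"labels": rm.labels, "probs": rm.probs.tolist()}
                for cfg, rm in r.rank_probability_means.items()
            }
        payload.append(entry)

    def _sanitize(obj):
        if isinstance(obj, dict):
            return {k: _sanitize(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_sanitize(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            return None if np.isnan(obj) else float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    with open(json_path, "w") as fh:
        json.dump(_sanitize(payload), fh, indent=2)
    return {"csv": str(csv_path), "json": str(json_path)}
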