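"""Posterior rank distributions and SUCRA for biomarker subgroups.

Subgroups are ranked per posterior draw by their treatment contrast
(rank 1 = largest gain in event-free days).  The rank-probability
matrix collects, for each subgroup j and rank r, the posterior
probability that j occupies r; SUCRA summarizes it as

    SUCRA_j = (1 / (J - 1)) * sum_{k=1}^{J-1} Pr(rank_j <= k),

equal to 1 for a certainly-best subgroup and 0 for a certainly-worst.

Two configurations mirror the two ways biomarker availability is used:
*marginal* (x1+/x1-/x2+/x2- from two single-biomarker fits on everyone
with that biomarker measured, draws paired across fits by index as
independent posteriors) and *joint* (++/+-/-+/-- from the complete-case
two-biomarker fit, draws aligned within the fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import EffectPosterior, arm_contrast
from .fit import PosteriorDraws

__all__ = [
    "RankMatrix",
    "SucraSummary",
    "rank_distribution",
    "sucra",
    "marginal_subgroup_effects",
    "joint_subgroup_effects",
    "plot_rank_bars",
]


@dataclass
class RankMatrix:
    """probs[j, r-1] = posterior probability subgroup j has rank r."""

    probs: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        J = len(self.labels)
        if self.probs.shape != (J, J):
            raise ValueError("rank matrix must be J x J")

    @property
    def J(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs,
            index=pd.Index(self.labels, name="subgroup"),
            columns=[f"rank_{r}" for r in range(1, self.J + 1)],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class SucraSummary:
    """SUCRA value per subgroup and the top-ranked subgroup label."""

    sucra: np.ndarray
    labels: list[str]

    @property
    def top_subgroup(self) -> str:
        return self.labels[int(np.argmax(self.sucra))]

    def to_series(self) -> pd.Series:
        return pd.Series(self.sucra, index=self.labels, name="sucra")


def rank_distribution(effects: list[EffectPosterior], rng=None) -> RankMatrix:
    """Posterior rank-probability matrix of subgroup treatment effects.

    Per draw index, subgroup effects are sorted descending and awarded
    ranks 1..J; exact ties are broken uniformly at random (seedable via
    ``rng``).  Rows are subgroups in input order.
    """
    if len(effects) < 2:
        raise ValueError("ranking needs at least two subgroups")
    lengths = {e.n_draws for e in effects}
    if len(lengths) != 1:
        raise ValueError("effects must have equal draw counts")
    E = np.column_stack([e.delta_draws for e in effects])  # (D, J)
    D, J = E.shape
    rng = np.random.default_rng(rng)
    tie_key = rng.uniform(size=(D, J))
    # lexsort: primary key -E (descending effect), secondary random
    order = np.lexsort((tie_key, -E), axis=-1)  # (D, J): positions by rank
    counts = np.zeros((J, J))
    for r in range(J):
        cnt = np.bincount(order[:, r], minlength=J)
        counts[:, r] = cnt
    probs = counts / D
    return RankMatrix(probs, [e.scope for e in effects])


def sucra(rm: RankMatrix) -> SucraSummary:
    """Surface under the cumulative ranking curve per subgroup."""
    if rm.J < 2:
        raise ValueError("SUCRA needs at least two subgroups")
    cum = np.cumsum(rm.probs, axis=1)[:, : rm.J - 1]
    vals = cum.sum(axis=1) / (rm.J - 1)
    return SucraSummary(vals, rm.labels)


def marginal_subgroup_effects(fit_x1: PosteriorDraws, fit_x2: PosteriorDraws,
                              records: pd.DataFrame) -> list[EffectPosterior]:
    """Effects for {x1+, x1-, x2+, x2-} from the two single-biomarker fits.

    Each fit used every patient with that biomarker measured; its two
    subgroup contrasts are standardized over the subgroup's members.
    Draws across the two fits are paired by index (independent
    posteriors).
    """
    if fit_x1 is None or fit_x2 is None:
        raise ValueError("both single-biomarker fits are required")
    effects = []
    for fit, col in ((fit_x1, "x1"), (fit_x2, "x2")):
        if tuple(fit.covariates) != (col,):
            raise ValueError(f"expected a {col}-only fit, got covariates {fit.covariates}")
        for value, sign in ((1.0, "+"), (0.0, "-")):
            mask = (records[col] == value).to_numpy()
            effects.append(
                arm_contrast(fit, records, scope=mask, scope_label=f"{col}{sign}")
            )
    return effects


def joint_subgroup_effects(fit_both: PosteriorDraws,
                           records: pd.DataFrame) -> list[EffectPosterior]:
    """Effects for {++, +-, -+, --} from the complete-case joint fit.

    All four contrasts share the same fit's aligned draws.  An empty
    cell falls back to the model-based contrast at that covariate
    pattern (no empirical standardization is needed: the cell pattern
    determines lambda exactly).
    """
    cov = tuple(fit_both.covariates)
    if len(cov) != 2:
        raise ValueError("joint ranking needs the two-biomarker fit")
    c1, c2 = cov
    complete = records.loc[records[[c1, c2]].notna().all(axis=1)]
    effects = []
    for v1, s1 in ((1.0, "+"), (0.0, "-")):
        for v2, s2 in ((1.0, "+"), (0.0, "-")):
            label = f"{s1}{s2}"
            mask = ((complete[c1] == v1) & (complete[c2] == v2)).to_numpy()
            if mask.any():
                eff = arm_contrast(fit_both, complete, scope=mask, scope_label=label)
            else:
                eff = arm_contrast(fit_both, complete, pattern=np.array([v1, v2]),
                                   scope_label=label)
            effects.append(eff)
    return effects


def plot_rank_bars(rank_matrices: dict[str, RankMatrix], path=None):
    """Stacked-bar chart of rank probabilities, one panel per config."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(rank_matrices)
    fig, axes = plt.subplots(1, n, figsize=(4.5 * n, 3.5), squeeze=False)
    for ax, (title, rm) in zip(axes[0], rank_matrices.items()):
        bottom = np.zeros(rm.J)
        x = np.arange(rm.J)
        for r in range(rm.J):
            ax.bar(x, rm.probs[:, r], bottom=bottom, label=f"rank {r + 1}")
            bottom += rm.probs[:, r]
        ax.set_xticks(x, rm.labels)
        ax.set_ylabel("probability")
        ax.set_title(title)
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
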