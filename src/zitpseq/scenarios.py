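"""Scenario catalogue and configuration I/O for the simulation study.

The shipped catalogue holds the six generative scenarios of the design's
simulation study (two Bernoulli(0.5) biomarkers, zero-inflation rate
phi = 0.30, truncation at G = 28 days, maximum enrollment 1800 with one
interim look at 500, efficacy rule delta = 2 days / epsilon = 0.995):

===  =======================================  =====  ====  ====  =====  ========  ========
No.  Name                                     beta0  b_x1  b_x2  b_T    b_int1    b_int2
===  =======================================  =====  ====  ====  =====  ========  ========
1    null                                     2.60   0.00  0.00  0.14   0.00      0.00
2    prognostic-x1                            2.60   0.20  0.00  0.14   0.00      0.00
3    predictive-x2                            2.60   0.00  0.00  0.14   0.00      0.10
4    prognostic-and-predictive                2.60   0.10  0.10  0.14   0.05      0.10
5    qualitative-quantitative-interactions    2.60   0.10  0.15  0.14   -0.25     0.05
6    qualitative-quantitative-interactions-2  2.60   0.10  0.15  0.20   -0.25     0.05
===  =======================================  =====  ====  ====  =====  ========  ========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .zitp import CoefficientVector

__all__ = ["ScenarioSpec", "SCENARIO_NAMES", "scenario_spec"]

#: gamma0 = logit(0.30): baseline log odds of an excess zero.
_GAMMA0_30 = float(np.log(0.30 / 0.70))


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one simulated trial configuration.

    Parameters
    ----------
    name : str
        Scenario label.
    coef : CoefficientVector
        True generative coefficients (gamma0 encodes the zero-inflation
        rate; ``coef.phi`` must equal ``phi``).
    prevalence : ndarray
        Probability of positivity per biomarker.
    phi : float
        Zero-inflation rate.
    G : int
        Truncation bound in days.
    N_max : int
        Maximum enrollment.
    interim_sizes : tuple[int, ...]
        Cumulative sample sizes at interim looks (strictly increasing,
        all < N_max); the final look is at N_max.
    delta : float
        Clinically relevant lambda-scale difference in days.
    epsilon : float
        Posterior-probability decision threshold (stop iff prob > epsilon,
        strict).
    allocation : float
        Probability of assignment to the experimental arm (1:1 -> 0.5).
    """

    name: str
    coef: CoefficientVector
    prevalence: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    phi: float = 0.30
    G: int = 28
    N_max: int = 1800
    interim_sizes: tuple = (500,)
    delta: float = 2.0
    epsilon: float = 0.995
    allocation: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "prevalence", np.asarray(self.prevalence, dtype=float))
        object.__setattr__(self, "interim_sizes", tuple(int(n) for n in self.interim_sizes))
        if self.prevalence.size != self.coef.m:
            raise ValueError("prevalence length must match number of biomarkers")
        if not np.all((self.prevalence > 0) & (self.prevalence < 1)):
            raise ValueError("prevalences must lie in (0, 1)")
        sizes = self.interim_sizes
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("interim_sizes must be strictly increasing")
        if sizes and sizes[-1] >= self.N_max:
            raise ValueError("all interim_sizes must be < N_max")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if not (self.delta > 0):
            raise ValueError("delta must be positive")
        if not (0.0 < self.allocation < 1.0):
            raise ValueError("allocation must lie in (0, 1)")

    @property
    def m(self) -> int:
        return self.coef.m

    @property
    def looks(self) -> tuple:
        """All analysis sample sizes: interims then the final at N_max."""
        return self.interim_sizes + (self.N_max,)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coef": {
                "beta0": self.coef.beta0,
                "beta_x": [float(v) for v in self.coef.beta_x],
                "beta_T": self.coef.beta_T,
                "beta_inter": [float(v) for v in self.coef.beta_inter],
                "gamma0": self.coef.gamma0,
            },
            "prevalence": [float(p) for p in self.prevalence],
            "phi": self.phi,
            "G": self.G,
            "N_max": self.N_max,
            "interim_sizes": list(self.interim_sizes),
            "delta": self.delta,
            "epsilon": self.epsilon,
            "allocation": self.allocation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        c = d["coef"]
        coef = CoefficientVector(
            beta0=c["beta0"],
            beta_x=np.asarray(c["beta_x"], dtype=float),
            beta_T=c["beta_T"],
            beta_inter=np.asarray(c["beta_inter"], dtype=float),
            gamma0=c["gamma0"],
        )
        kwargs = {k: d[k] for k in
                  ("prevalence", "phi", "G", "N_max", "interim_sizes",
                   "delta", "epsilon", "allocation") if k in d}
        return cls(name=d["name"], coef=coef, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _coef(beta0, b1, b2, bT, bi1, bi2) -> CoefficientVector:
    return CoefficientVector(
        beta0=beta0,
        beta_x=np.array([b1, b2]),
        beta_T=bT,
        beta_inter=np.array([bi1, bi2]),
        gamma0=_GAMMA0_30,
    )


_CATALOGUE = {
    1: ("null", _coef(2.60, 0.00, 0.00, 0.14, 0.00, 0.00)),
    2: ("prognostic-x1", _coef(2.60, 0.20, 0.00, 0.14, 0.00, 0.00)),
    3: ("predictive-x2", _coef(2.60, 0.00, 0.00, 0.14, 0.00, 0.10)),
    4: ("prognostic-and-predictive", _coef(2.60, 0.10, 0.10, 0.14, 0.05, 0.10)),
    5: ("qualitative-quantitative-interactions", _coef(2.60, 0.10, 0.15, 0.14, -0.25, 0.05)),
    6: ("qualitative-quantitative-interactions-2", _coef(2.60, 0.10, 0.15, 0.20, -0.25, 0.05)),
}

SCENARIO_NAMES = {num: name for num, (name, _) in _CATALOGUE.items()}


def scenario_spec(scenario: int | str, prevalence_x2: float = 0.5, **overrides) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from the shipped catalogue.

    ``scenario`` is a catalogue number (1..6) or name.  ``prevalence_x2``
    varies the positivity rate of the second biomarker (the sensitivity
    axis of the study); x1 prevalence stays at 0.5.  Remaining keyword
    overrides are forwarded to :class:`ScenarioSpec`.
    """
    if isinstance(scenario, str):
        by_name = {name: num for num, name in SCENARIO_NAMES.items()}
        if scenario not in by_name:
            raise KeyError(f"unknown scenario {scenario!r}")
        scenario = by_name[scenario]
    if scenario not in _CATALOGUE:
        raise KeyError(f"unknown scenario number {scenario}; catalogue has 1..6")
    name, coef = _CATALOGUE[scenario]
    spec = ScenarioSpec(
        name=name,
        coef=coef,
        prevalence=np.array([0.5, float(prevalence_x2)]),
    )
    return replace(spec, **overrides) if overrides else spec
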