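"""Zero-inflated truncated Poisson (ZITP) distribution kernel.

The ZITP model mixes a point mass at zero (probability ``phi``, the
zero-inflation rate) with a Poisson distribution renormalized to the
support ``{0, ..., G}``:

    P(Y = 0) = phi + (1 - phi) * f(0)
    P(Y = y) = (1 - phi) * f(y),          1 <= y <= G

where ``f(y) = (lambda^y / y!) / sum_{z=0}^{G} lambda^z / z!`` is the
truncated Poisson density.  This endpoint shape arises for "event-free
days out of G" outcomes in intensive-care trials: deaths are scored 0
(hence the excess zeros) and follow-up stops at G = 28 days (hence the
right truncation).

Two distinct mechanisms live side by side in this module on purpose:

* :func:`zitp_pmf` is the renormalized-truncation density used by the
  likelihood, and
* :func:`zitp_rng` generates data by *censoring* a standard Poisson draw
  at G (``R = min(W, G)``) before applying the zero-inflation coin.

The two coincide only when ``P(W > G)`` is negligible; both are kept
because the simulation study generates with the censored mechanism but
analyzes with the truncated likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logsumexp

__all__ = [
    "ZITPParams",
    "CoefficientVector",
    "BiomarkerProfile",
    "truncated_poisson_logpmf",
    "truncated_poisson_pmf",
    "zitp_logpmf",
    "zitp_pmf",
    "zitp_mean",
    "zitp_rng",
    "linear_predictor",
]


@dataclass(frozen=True)
class ZITPParams:
    """Parameters of a single ZITP distribution.

    Parameters
    ----------
    lambda_ : float
        Mean of the underlying (untruncated) Poisson, in days. Must be > 0.
    phi : float
        Excess-zero probability, in [0, 1].
    G : int
        Truncation bound (days); the support is {0, ..., G}. Must be >= 1
        for a nondegenerate support, >= 0 is accepted (G = 0 puts all
        truncated-Poisson mass at zero).
    """

    lambda_: float
    phi: float
    G: int

    def __post_init__(self) -> None:
        if not (self.lambda_ > 0) or not math.isfinite(self.lambda_):
            raise ValueError(f"lambda_ must be a finite positive real, got {self.lambda_}")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if int(self.G) != self.G or self.G < 0:
            raise ValueError(f"G must be a nonnegative integer, got {self.G}")


def _check_lambda_G(lambda_: float, G: int) -> None:
    if not (lambda_ > 0):
        raise ValueError(f"lambda_ must be positive, got {lambda_}")
    if int(G) != G or G < 0:
        raise ValueError(f"G must be a nonnegative integer, got {G}")


def truncated_poisson_logpmf(y, lambda_: float, G: int):
    """Log pmf of the Poisson distribution truncated to {0, ..., G}.

    Evaluated fully in log space: the normalizer
    ``log sum_{z=0}^G exp(z log lambda - log z!)`` uses log-sum-exp so that
    e.g. ``lambda^28 / 28!`` never materializes.
    """
    _check_lambda_G(lambda_, G)
    y = np.asarray(y)
    if np.any((y < 0) | (y > G)) or not np.issubdtype(y.dtype, np.number):
        raise ValueError(f"y must lie in [0, {G}]")
    if np.any(y != np.floor(y)):
        raise ValueError("y must be integer-valued")
    z = np.arange(G + 1)
    log_norm = logsumexp(z * np.log(lambda_) - gammaln(z + 1))
    return y * np.log(lambda_) - gammaln(np.asarray(y, dtype=float) + 1) - log_norm


def truncated_poisson_pmf(y, lambda_: float, G: int):
    """Pmf of the Poisson distribution truncated (renormalized) to {0..G}."""
    return np.exp(truncated_poisson_logpmf(y, lambda_, G))


def zitp_logpmf(y, params: ZITPParams):
    """Log pmf of the zero-inflated truncated Poisson."""
    y = np.asarray(y)
    tp = truncated_poisson_logpmf(y, params.lambda_, params.G)
    phi = params.phi
    if phi == 0.0:
        return tp
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0,
            np.log(phi + (1.0 - phi) * np.exp(tp)),
            (np.log1p(-phi) if phi < 1.0 else -np.inf) + tp,
        )
    return out


def zitp_pmf(y, params: ZITPParams):
    """Pmf of the zero-inflated truncated Poisson on {0, ..., G}."""
    return np.exp(zitp_logpmf(y, params))


def zitp_mean(params: ZITPParams) -> float:
    """Expected number of event-free days, ``(1-phi) * sum_y y f(y)``."""
    y = np.arange(params.G + 1)
    f = truncated_poisson_pmf(y, params.lambda_, params.G)
    return float((1.0 - params.phi) * np.sum(y * f))


def zitp_rng(params: ZITPParams, n: int, seed=None) -> np.ndarray:
    """Generate ZITP outcomes by the censoring mechanism.

    For each draw: ``W ~ Poisson(lambda_)``, ``R = min(W, G)``,
    ``U ~ Uniform[0,1]``; return 0 if ``U < phi`` else ``R``.

    Note this censors at G rather than renormalizing the truncated tail;
    it matches :func:`zitp_pmf` only when ``P(W > G)`` is negligible.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    w = rng.poisson(params.lambda_, size=n)
    r = np.minimum(w, params.G)
    u = rng.uniform(size=n)
    return np.where(u < params.phi, 0, r).astype(np.int64)


@dataclass(frozen=True)
class BiomarkerProfile:
    """Tri-state biomarker vector: 1.0 positive, 0.0 negative, NaN missing."""

    values: np.ndarray

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        object.__setattr__(self, "values", arr)

    def require_one_measured(self) -> "BiomarkerProfile":
        if self.values.size and np.all(np.isnan(self.values)):
            raise ValueError("trial subjects must have at least one measured biomarker")
        return self

    @property
    def m(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class CoefficientVector:
    """Regression coefficients of the ZITP model.

    ``log(lambda_i) = beta0 + sum_j beta_x[j] x_ji + beta_T T_i
                    + sum_j beta_inter[j] x_ji T_i``  and
    ``logit(phi) = gamma0``.

    A missing biomarker contributes zero to the linear predictor (its main
    effect and interaction are dropped for that subject).
    """

    beta0: float
    beta_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_T: float = 0.0
    beta_inter: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_x", np.asarray(self.beta_x, dtype=float))
        object.__setattr__(self, "beta_inter", np.asarray(self.beta_inter, dtype=float))
        if self.beta_x.shape != self.beta_inter.shape or self.beta_x.ndim != 1:
            raise ValueError("beta_x and beta_inter must be 1-D vectors of equal length")
        vals = np.concatenate(
            [[self.beta0, self.beta_T, self.gamma0], self.beta_x, self.beta_inter]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("all coefficients must be finite")

    @property
    def m(self) -> int:
        return int(self.beta_x.size)

    @property
    def phi(self) -> float:
        """Zero-inflation rate implied by gamma0 (intercept-only logit)."""
        return float(expit(self.gamma0))


def linear_predictor(coef: CoefficientVector, profile, treatment) -> np.ndarray | float:
    """Poisson mean ``lambda`` implied by a biomarker profile and arm.

    ``profile`` is a tri-state vector (or n x m matrix) with NaN marking a
    missing biomarker; missing entries contribute nothing to the linear
    predictor (their main effect and treatment interaction are zeroed).
    Returns ``exp`` of the linear combination.
    """
    if isinstance(profile, BiomarkerProfile):
        profile = profile.values
    x = np.asarray(profile, dtype=float)
    scalar = x.ndim <= 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != coef.m:
        raise ValueError(f"profile has {x2.shape[1]} biomarkers, coefficients have {coef.m}")
    t = np.asarray(treatment, dtype=float)
    xz = np.nan_to_num(x2, nan=0.0)  # missing -> zero contribution
    eta = (
        coef.beta0
        + xz @ coef.beta_x
        + coef.beta_T * t
        + (xz @ coef.beta_inter) * t
    )
    lam = np.exp(eta)
    return float(lam[0]) if (scalar and lam.size == 1) else lam
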