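"""Numba-compiled adaptive random-walk Metropolis-within-Gibbs kernel.

The target is the exact ZITP regression posterior: mixture likelihood
(point mass at zero + renormalized truncated Poisson) times independent
normal priors on every coefficient and on gamma0.

Subjects are collapsed to unique covariate patterns before sampling.
Because the zero-inflation rate is intercept-only, the log likelihood
depends on the data only through, per pattern: the number of zero
outcomes ``n0``, the number of positive outcomes ``npos`` and their sum
``S``.  Constant terms (sum of log y!) are dropped; they cancel in every
Metropolis ratio.  This makes one likelihood evaluation O(patterns x G)
regardless of sample size.

Each iteration is one per-parameter random-walk sweep (step sizes
adapted toward a 0.44 acceptance rate during burn-in, Robbins–Monro on
the log scale) followed by one joint random-walk update of the whole
parameter vector whose proposal covariance is the empirical covariance
of the burn-in history (Haario-style, rescaled toward a 0.28 acceptance
rate).  All adaptation freezes at the end of burn-in, so the kept draws
come from a fixed, valid Metropolis kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["collapsed_loglik", "run_chain"]

_TARGET_ACC = 0.44


@njit(cache=True)
def _loglik(eta, phi, logfact, G, n0, npos, S):
    ll = 0.0
    P = eta.shape[0]
    for p in range(P):
        # log normalizer of the truncated Poisson at this pattern
        mx = -1.0e300
        for z in range(G + 1):
            t = z * eta[p] - logfact[z]
            if t > mx:
                mx = t
        s = 0.0
        for z in range(G + 1):
            s += np.exp(z * eta[p] - logfact[z] - mx)
        logC = mx + np.log(s)
        if n0[p] > 0.0:
            f0 = np.exp(-logC)
            pz = phi + (1.0 - phi) * f0
            if pz <= 0.0:
                return -np.inf
            ll += n0[p] * np.log(pz)
        if npos[p] > 0.0:
            if phi >= 1.0:
                return -np.inf
            ll += npos[p] * (np.log(1.0 - phi) - logC) + S[p] * eta[p]
    return ll


def collapsed_loglik(eta, phi, logfact, G, n0, npos, S):
    """Python-facing wrapper around the collapsed log likelihood
    (constant ``-sum log y!`` terms omitted)."""
    return _loglik(
        np.asarray(eta, dtype=np.float64),
        float(phi),
        np.asarray(logfact, dtype=np.float64),
        int(G),
        np.asarray(n0, dtype=np.float64),
        np.asarray(npos, dtype=np.float64),
        np.asarray(S, dtype=np.float64),
    )


@njit(cache=True)
def run_chain(Xp, n0, npos, S, G, logfact, prior_mean, prior_sd,
              init, n_burn, n_keep, thin, seed, step_init):
    """One MCMC chain; returns (draws [n_keep x d], acceptance rates).

    Parameter order: regression coefficients (design columns of ``Xp``)
    then gamma0 last.
    """
    np.random.seed(seed)
    P, p = Xp.shape
    d = p + 1
    theta = init.copy()
    eta = Xp @ theta[:p] if P > 0 else np.zeros(0)
    phi = 1.0 / (1.0 + np.exp(-theta[p]))
    ll = _loglik(eta, phi, logfact, G, n0, npos, S)
    ls = np.log(step_init) * np.ones(d)
    draws = np.empty((n_keep, d))
    acc = np.zeros(d)
    total = n_burn + n_keep * thin
    kept = 0
    # joint-update machinery: empirical covariance of the burn-in history
    hist = np.empty((n_burn, d))
    chol = np.eye(d)
    have_chol = False
    ls_joint = 0.0  # log scale multiplying 2.38/sqrt(d)
    base = 2.38 / np.sqrt(d)
    for t in range(total):
        for j in range(d):
            prop = theta[j] + np.exp(ls[j]) * np.random.normal()
            if j < p:
                eta_new = eta + (prop - theta[j]) * Xp[:, j]
                phi_new = phi
            else:
                eta_new = eta
                phi_new = 1.0 / (1.0 + np.exp(-prop))
            ll_new = _loglik(eta_new, phi_new, logfact, G, n0, npos, S)
            logr = (
                ll_new - ll
                - 0.5 * ((prop - prior_mean[j]) / prior_sd[j]) ** 2
                + 0.5 * ((theta[j] - prior_mean[j]) / prior_sd[j]) ** 2
            )
            a = np.exp(logr) if logr < 0.0 else 1.0
            if np.random.random() < a:
                theta[j] = prop
                ll = ll_new
                if j < p:
                    eta = eta_new
                else:
                    phi = phi_new
                acc[j] += 1.0
            if t < n_burn:
                gain = 1.0 / np.sqrt(t + 1.0)
                if gain > 0.1:
                    gain = 0.1
                ls[j] += gain * (a - _TARGET_ACC)
        # joint move along the adapted covariance
        if have_chol:
            z = np.empty(d)
            for j in range(d):
                z[j] = np.random.normal()
            step = base * np.exp(ls_joint)
            prop_v = theta + step * (chol @ z)
            eta_new = Xp @ prop_v[:p] if P > 0 else eta
            phi_new = 1.0 / (1.0 + np.exp(-prop_v[d - 1]))
            ll_new = _loglik(eta_new, phi_new, logfact, G, n0, npos, S)
            lpr = 0.0
            for j in range(d):
                lpr += (
                    -0.5 * ((prop_v[j] - prior_mean[j]) / prior_sd[j]) ** 2
                    + 0.5 * ((theta[j] - prior_mean[j]) / prior_sd[j]) ** 2
                )
            logr = ll_new - ll + lpr
            a = np.exp(logr) if logr < 0.0 else 1.0
            if np.random.random() < a:
                theta = prop_v
                eta = eta_new
                phi = phi_new
                ll = ll_new
            if t < n_burn:
                gain = 1.0 / np.sqrt(t + 1.0)
                if gain > 0.1:
                    gain = 0.1
                ls_joint += gain * (a - 0.28)
        if t < n_burn:
            for j in range(d):
                hist[t, j] = theta[j]
            if t >= 199 and (t + 1) % 100 == 0:
                cov = np.cov(hist[: t + 1].T) + 1e-10 * np.eye(d)
                chol = np.linalg.cholesky(cov)
                have_chol = True
        if t >= n_burn and (t - n_burn) % thin == 0:
            for j in range(d):
                draws[kept, j] = theta[j]
            kept += 1
    return draws, acc / total
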