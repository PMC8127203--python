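"""Adaptive Gauss-Hermite quadrature for random-intercept integrals.

The integrals needed throughout the package have the form

    A = int L(b) phi(b; E, SD) db,

with L a Bernoulli-logit or Poisson-log likelihood in the intercept b. When
the history is informative the integrand is much narrower than the
random-effects distribution, so nodes are centered at the mode of
log L(b) + log phi(b) with scale from its curvature (the integrand is
strictly log-concave for both families, so Newton iterations with damped
steps always converge). All outputs are log-scale.

Sufficient statistics keep the cost low: for Poisson the likelihood depends
on b only through (sum of counts s, sum of rate multipliers S); for
Bernoulli through (s, the linear-predictor row), so units sharing a
covariate pattern and event count are interchangeable.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, logsumexp

_LOG_2PI = np.log(2.0 * np.pi)


def hermite_rule(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw Gauss-Hermite nodes and log-weights for int e^{-x^2} f(x) dx."""
    x, w = hermgauss(n_nodes)
    return x, np.log(w)


def _log_phi(b, E, SD):
    return -0.5 * ((b - E) / SD) ** 2 - np.log(SD) - 0.5 * _LOG_2PI


def bernoulli_marginal(
    mu: np.ndarray,
    s: np.ndarray,
    E: np.ndarray,
    SD: np.ndarray,
    x: np.ndarray,
    logw: np.ndarray,
    n_newton: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive marginal integral for Bernoulli-logit units.

    mu: (..., T) linear predictors excluding b; s: (...,) event counts;
    E, SD broadcastable to (...,). Returns (logA, bhat, bmode): logA is
    log of int exp(s*b - sum_t log(1+e^{mu_t+b})) phi(b) db; bhat and bmode
    are the posterior mean and mode of b.
    """
    T = mu.shape[-1]
    s = np.asarray(s, dtype=float)
    # start near the empirical logit, shifted by the mean predictor
    b = np.log((s + 0.5) / (T - s + 0.5)) - mu.mean(axis=-1)
    b = np.broadcast_to(b + 0.0 * (E + SD), np.broadcast_shapes(b.shape, np.shape(E))).copy()
    for _ in range(n_newton):
        p = expit(mu + b[..., None])
        f1 = s - p.sum(axis=-1) - (b - E) / SD**2
        f2 = -(p * (1.0 - p)).sum(axis=-1) - 1.0 / SD**2
        b -= np.clip(f1 / f2, -4.0, 4.0)
    p = expit(mu + b[..., None])
    f2 = -(p * (1.0 - p)).sum(axis=-1) - 1.0 / SD**2
    tau = 1.0 / np.sqrt(-f2)

    nodes = b[..., None] + np.sqrt(2.0) * tau[..., None] * x  # (..., Q)
    with np.errstate(over="ignore"):
        C = np.logaddexp(0.0, mu[..., None, :] + nodes[..., :, None]).sum(axis=-1)
        integrand = (
            logw
            + x**2
            + s[..., None] * nodes
            - C
            + _log_phi(nodes, np.asarray(E)[..., None], np.asarray(SD)[..., None])
        )
        logA = logsumexp(integrand, axis=-1) + 0.5 * np.log(2.0) + np.log(tau)
        post = np.exp(integrand - logsumexp(integrand, axis=-1)[..., None])
    bhat = (post * nodes).sum(axis=-1)
    return logA, bhat, b


def bernoulli_loglik_at(mu: np.ndarray, s: np.ndarray, b: np.ndarray) -> np.ndarray:
    """s*b - sum_t log(1+e^{mu_t+b}) evaluated at a given intercept."""
    with np.errstate(over="ignore"):
        C = np.logaddexp(0.0, mu + b[..., None]).sum(axis=-1)
    return np.asarray(s, dtype=float) * b - C


def poisson_marginal(
    S: np.ndarray,
    s: np.ndarray,
    E: np.ndarray,
    SD: np.ndarray,
    x: np.ndarray,
    logw: np.ndarray,
    n_newton: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive marginal integral for Poisson-log units.

    S: (...,) summed rate multipliers sum_t e^{mu_t}; s: (...,) summed
    counts. Returns (logA, bhat, bmode) with logA the log of
    int exp(s*b - S e^b) phi(b) db (count factorials excluded) and bhat /
    bmode the posterior mean and mode of b.
    """
    S = np.asarray(S, dtype=float)
    s = np.asarray(s, dtype=float)
    b = np.minimum(np.log((s + 0.5) / S), E + s * SD**2)
    b = np.broadcast_to(b, np.broadcast_shapes(b.shape, np.shape(E))).copy()
    for _ in range(n_newton):
        lam = S * np.exp(b)
        f1 = s - lam - (b - E) / SD**2
        f2 = -lam - 1.0 / SD**2
        b -= np.clip(f1 / f2, -4.0, 4.0)
    tau = 1.0 / np.sqrt(S * np.exp(b) + 1.0 / SD**2)

    nodes = b[..., None] + np.sqrt(2.0) * tau[..., None] * x
    with np.errstate(over="ignore"):
        integrand = (
            logw
            + x**2
            + s[..., None] * nodes
            - S[..., None] * np.exp(nodes)
            + _log_phi(nodes, np.asarray(E)[..., None], np.asarray(SD)[..., None])
        )
        logA = logsumexp(integrand, axis=-1) + 0.5 * np.log(2.0) + np.log(tau)
        post = np.exp(integrand - logsumexp(integrand, axis=-1)[..., None])
    bhat = (post * nodes).sum(axis=-1)
    return logA, bhat, b


def poisson_loglik_at(S: np.ndarray, s: np.ndarray, b: np.ndarray) -> np.ndarray:
    """s*b - S e^b evaluated at a given intercept (factorials excluded)."""
    with np.errstate(over="ignore"):
        return np.asarray(s, dtype=float) * b - np.asarray(S, dtype=float) * np.exp(b)
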