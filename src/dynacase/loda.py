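"""Longitudinal discriminant analysis: group-membership probabilities.

Given MCMC draws of each group's MGLMM parameters, the probability that an
individual with accrued marker history y_{1..j} belongs to the case group is,
per draw and by Bayes' theorem,

    P_case = pi_case f_case / (pi_case f_case + pi_control f_control),

where f_g is a predictive density of the history under group g's model and
pi_g are prior group probabilities (0.5/0.5 by default). Three predictive
densities are supported:

* marginal        — random intercepts integrated out (Gauss-Hermite);
* conditional     — likelihood evaluated at the estimated intercept b-hat
                    (its posterior mean given the accrued history);
* random_effects  — density of b-hat under the group's random-effects
                    distribution, product over markers.

All density work is carried out in log space (15 Bernoulli/Poisson terms
underflow in linear space), and each draw uses its own parameters so the
spread of the per-draw probabilities is a credible interval for P_case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from . import _agq
from .grid import DEFAULT_GRID, OccasionGrid
from .mglmm import MGLMMSpec, PosteriorDraws, build_marker_arrays
from .simdata import IndividualRecord

_log = logging.getLogger(__name__)

APPROACHES = ("marginal", "conditional", "random_effects")


# ---------------------------------------------------------------------------
# per-marker predictive log-densities


def _log_phi(b, mean, sd):
    return -0.5 * ((b - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def marker_log_densities(
    Y: np.ndarray,
    X: np.ndarray,
    family: str,
    alpha: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    approach: str = "marginal",
    n_nodes: int = 31,
    occasions: str = "all",
    b_estimator: str = "mean",
) -> np.ndarray:
    """Cumulative predictive log-density of each history prefix.

    Y (n, J), X (n, J, p); per-draw parameters alpha (M, p), mean (M,),
    sd (M,). Returns (n, J, M): entry [i, j, m] is the log predictive
    density of individual i's history through occasion j under draw m
    (adaptive Gauss-Hermite for the marginal integral and for the estimated
    intercept b-hat used by the conditional / random-effects approaches;
    ``b_estimator`` picks the posterior mean or mode of the intercept).
    With ``occasions="final"`` only the last occasion's column is computed
    (earlier columns are left at -inf), which is substantially cheaper.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    if occasions not in ("all", "final"):
        raise ValueError("occasions must be 'all' or 'final'")
    if b_estimator not in ("mean", "mode"):
        raise ValueError("b_estimator must be 'mean' or 'mode'")
    Y = np.asarray(Y, dtype=float)
    n, J = Y.shape
    alpha = np.asarray(alpha, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    M = len(mean)
    x, logw = _agq.hermite_rule(n_nodes)
    eta0 = np.einsum("njp,mp->njm", np.asarray(X, dtype=float), alpha)  # (n, J, M)

    out = np.full((n, J, M), -np.inf)
    active = range(J - 1, J) if occasions == "final" else range(J)
    bernoulli = family == "bernoulli_logit"

    cum_s = np.zeros(n)
    cum_ymu = np.zeros((n, M))
    if bernoulli:
        # collapse individuals to (covariate pattern, cumulative count) groups
        X = np.asarray(X, dtype=float)
        if X.shape[2] == 0:
            pat_X = np.zeros((1, J, 0))
            pat_idx = np.zeros(n, dtype=int)
        else:
            flat = np.ascontiguousarray(X).reshape(n, -1)
            pat_rows, pat_idx = np.unique(flat, axis=0, return_inverse=True)
            pat_X = pat_rows.reshape(-1, J, X.shape[2])
        mu_pat = np.einsum("pjq,mq->pjm", pat_X, alpha)  # (P, J, M)
    else:
        cum_S = np.zeros((n, M))

    for j in range(J):
        cum_ymu += Y[:, j][:, None] * eta0[:, j, :]
        cum_s += Y[:, j]
        if not bernoulli:
            with np.errstate(over="ignore"):
                cum_S += np.exp(eta0[:, j, :])
        if j not in active:
            continue

        if bernoulli:
            key = pat_idx * (J + 2) + cum_s.astype(int)
            _, first, inv = np.unique(key, return_index=True, return_inverse=True)
            g_pat = pat_idx[first]
            g_s = cum_s[first]
            mu_g = np.moveaxis(mu_pat[g_pat][:, : j + 1, :], 1, -1)  # (G, M, j+1)
            logA, bhat, bmode = _agq.bernoulli_marginal(
                mu_g, g_s[:, None], mean, sd, x, logw
            )
            if b_estimator == "mode":
                bhat = bmode
            if approach == "marginal":
                out[:, j] = cum_ymu + logA[inv]
            elif approach == "random_effects":
                out[:, j] = _log_phi(bhat, mean, sd)[inv]
            else:  # conditional
                ll_g = _agq.bernoulli_loglik_at(mu_g, g_s[:, None], bhat)
                out[:, j] = cum_ymu + ll_g[inv]
        else:
            const = -gammaln(Y[:, : j + 1] + 1.0).sum(axis=1)  # (n,)
            logA, bhat, bmode = _agq.poisson_marginal(
                cum_S, cum_s[:, None], mean, sd, x, logw
            )
            if b_estimator == "mode":
                bhat = bmode
            if approach == "marginal":
                out[:, j] = cum_ymu + const[:, None] + logA
            elif approach == "random_effects":
                out[:, j] = _log_phi(bhat, mean, sd)
            else:  # conditional
                ll = _agq.poisson_loglik_at(cum_S, cum_s[:, None], bhat)
                out[:, j] = cum_ymu + const[:, None] + ll
    return out


def predictive_log_density(
    y_history: np.ndarray,
    x_history: np.ndarray,
    family: str,
    alpha: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    approach: str = "marginal",
    n_nodes: int = 31,
) -> np.ndarray:
    """Per-draw log predictive density of one individual's single-marker
    history (occasions 1..j). Thin wrapper over :func:`marker_log_densities`."""
    y = np.atleast_1d(np.asarray(y_history, dtype=float))
    if y.size == 0:
        raise ValueError("history must be non-empty")
    X = np.asarray(x_history, dtype=float)[None, :, :]
    out = marker_log_densities(
        y[None, :], X, family, alpha, np.asarray(mean, float), np.asarray(sd, float),
        approach, n_nodes,
    )
    return out[0, -1, :]


# ---------------------------------------------------------------------------
# Bayes combination


@dataclass
class GroupProbabilities:
    """Per-draw case-membership probabilities for one batch of histories."""

    p_draws: np.ndarray  # (..., M), nan where both densities vanished
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_draws_used: np.ndarray


def group_probabilities(
    logf_case: np.ndarray,
    logf_control: np.ndarray,
    priors: tuple[float, float] = (0.5, 0.5),
    cri_level: float = 0.99,
) -> GroupProbabilities:
    """Combine per-draw log predictive densities via Bayes' theorem.

    Arrays may be (..., M); draws where both log-densities are -inf are
    skipped (with a logged count). The point estimate is the mean over draws
    and the credible interval the equal-tailed quantiles at ``cri_level``.
    """
    logf_case = np.asarray(logf_case, dtype=float)
    logf_control = np.asarray(logf_control, dtype=float)
    if logf_case.shape != logf_control.shape:
        raise ValueError("case and control densities must have equal draw counts")
    pi_case, pi_control = priors
    if not (pi_case > 0 or pi_control > 0) or pi_case < 0 or pi_control < 0:
        raise ValueError("priors must be non-negative and not both zero")
    if abs(pi_case + pi_control - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    if not (0 < cri_level < 1):
        raise ValueError("cri_level must be in (0, 1)")

    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.log(pi_case) + logf_case
        c = np.log(pi_control) + logf_control
        both_dead = np.isneginf(a) & np.isneginf(c)
        p = expit(a - c)
    p = np.where(both_dead, np.nan, p)
    n_skipped = int(both_dead.sum())
    if n_skipped:
        _log.info("group_probabilities: skipped %d draws with vanishing densities", n_skipped)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan slices stay nan
        point = np.nanmean(p, axis=-1)
        tail = (1.0 - cri_level) / 2.0
        lower = np.nanquantile(p, tail, axis=-1)
        upper = np.nanquantile(p, 1.0 - tail, axis=-1)
    n_used = np.sum(~np.isnan(p), axis=-1)
    return GroupProbabilities(p, point, lower, upper, n_used)


# ---------------------------------------------------------------------------
# cohort-level probability series


@dataclass
class ProbabilitySeries:
    """Per-occasion case-membership probabilities for one individual."""

    person_id: object
    approach: str
    priors: tuple[float, float]
    cri_level: float
    point: np.ndarray  # (J,)
    lower: np.ndarray
    upper: np.ndarray
    n_draws_used: np.ndarray
    draws: np.ndarray | None = None  # (J, M) if stored

    @property
    def n_occasions(self) -> int:
        return len(self.point)

    def with_cri_level(self, cri_level: float) -> "ProbabilitySeries":
        """Recompute the credible interval at another level (needs draws)."""
        if self.draws is None:
            raise ValueError("per-draw probabilities were not stored")
        tail = (1.0 - cri_level) / 2.0
        with np.errstate(invalid="ignore"):
            lower = np.nanquantile(self.draws, tail, axis=-1)
            upper = np.nanquantile(self.draws, 1.0 - tail, axis=-1)
        return ProbabilitySeries(
            self.person_id, self.approach, self.priors, cri_level,
            self.point.copy(), lower, upper, self.n_draws_used.copy(),
            self.draws,
        )


def compute_probability_series(
    individuals: list[IndividualRecord],
    draws_case: PosteriorDraws,
    draws_control: PosteriorDraws,
    approach: str = "random_effects",
    priors: tuple[float, float] = (0.5, 0.5),
    cri_level: float = 0.99,
    grid: OccasionGrid = DEFAULT_GRID,
    n_nodes: int = 31,
    store_draws: bool = False,
    occasions: str = "all",
    b_estimator: str = "mean",
) -> list[ProbabilitySeries]:
    """Case-membership probability series for every individual, all occasions.

    The two groups' draws must come from the same model specification and
    have equal draw counts (fit both groups with the same MCMC settings).
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    spec: MGLMMSpec = draws_case.spec
    if tuple(m.name for m in spec.markers) != tuple(
        m.name for m in draws_control.spec.markers
    ):
        raise ValueError("case and control draws use different model specs")
    if draws_case.n_draws != draws_control.n_draws:
        raise ValueError("case and control draw counts differ")
    n, J, M = len(individuals), grid.n_occasions, draws_case.n_draws
    if n == 0:
        return []

    logf = {}
    for label, draws in (("case", draws_case), ("control", draws_control)):
        acc = np.zeros((n, J, M))
        for mspec in spec.markers:
            md = draws.markers[mspec.name]
            p = len(mspec.covariates)
            Y, X = build_marker_arrays(individuals, mspec, grid)
            acc += marker_log_densities(
                Y, X, mspec.family,
                md.values[:, :p], md.column("intercept_mean"), md.column("intercept_sd"),
                approach, n_nodes, occasions, b_estimator,
            )
        logf[label] = acc

    gp = group_probabilities(logf["case"], logf["control"], priors, cri_level)
    series = []
    for i, ind in enumerate(individuals):
        series.append(
            ProbabilitySeries(
                person_id=ind.person_id,
                approach=approach,
                priors=priors,
                cri_level=cri_level,
                point=gp.point[i],
                lower=gp.lower[i],
                upper=gp.upper[i],
                n_draws_used=gp.n_draws_used[i],
                draws=gp.p_draws[i] if store_draws else None,
            )
        )
    return series


def series_to_frame(series: list[ProbabilitySeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for j in range(s.n_occasions):
            rows.append(
                {
                    "person_id": s.person_id,
                    "occasion": j + 1,
                    "approach": s.approach,
                    "p_point": s.point[j],
                    "p_lo": s.lower[j],
                    "p_hi": s.upper[j],
                    "n_draws_used": int(s.n_draws_used[j]),
                }
            )
    return pd.DataFrame(rows)
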