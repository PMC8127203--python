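"""Group-specific multivariate generalized linear mixed models (MGLMM).

Each utilization marker Y_{i,r,j} follows a Bernoulli-logit or Poisson-log
model with fixed effects for sex, region and age and an individual random
intercept b_{i,r} ~ N(mean_r, sd_r^2). The random-effects covariance across
markers is diagonal, so given the covariates the per-marker models factorize
and each marker is fit independently; the joint group model is their product.

Estimation is Bayesian. The random intercepts are integrated out of each
marker's likelihood with Gauss-Hermite quadrature, leaving a low-dimensional
posterior over (fixed effects, intercept mean, log intercept SD). That
posterior is sampled with an independence Metropolis-Hastings chain whose
proposal is a multivariate-t built from a Laplace approximation at the
posterior mode — near-iid draws for the near-Gaussian posteriors that arise
at the cohort sizes this package targets. Priors are weakly informative on
the link scale: Normal(0, 10^2) for fixed effects and the intercept mean,
Half-Normal(5) for the intercept SD.

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor (point estimate and upper confidence limit); model fit with the
penalized expected deviance (expected deviance plus an optimism penalty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln

from . import _agq
from .grid import DEFAULT_GRID, OccasionGrid
from .simdata import FAMILY_BY_MARKER, MARKER_ORDER, IndividualRecord

_log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    family: str  # bernoulli_logit | poisson_log
    covariates: tuple[str, ...] = ("male", "urban", "age")

    def __post_init__(self):
        if self.family not in ("bernoulli_logit", "poisson_log"):
            raise ValueError(f"unknown family {self.family!r}")
        unknown = set(self.covariates) - {"male", "urban", "age"}
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")


@dataclass(frozen=True)
class MGLMMSpec:
    """Markers, their families/covariates, and the (weak) prior scales."""

    markers: tuple[MarkerSpec, ...]
    n_mixture_components: int = 1
    prior_fixed_sd: float = 10.0
    prior_intercept_mean_sd: float = 10.0
    prior_intercept_sd_scale: float = 5.0

    def __post_init__(self):
        if not self.markers:
            raise ValueError("at least one marker is required")
        if self.n_mixture_components != 1:
            raise NotImplementedError(
                "only a single normal mixture component is supported"
            )


def _mspec(name: str, covariates=("male", "urban", "age")) -> MarkerSpec:
    return MarkerSpec(name, FAMILY_BY_MARKER[name], tuple(covariates))


#: Single-marker model: any JA-related healthcare contact.
JA_UTILIZATION_MODEL = MGLMMSpec(markers=(_mspec("ja_contact"),))
#: All four utilization markers.
FULL_MODEL = MGLMMSpec(markers=tuple(_mspec(m) for m in MARKER_ORDER))


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 10000
    burn_in: int = 1000
    thinning: int = 100
    n_chains: int = 2
    seed: int = 0
    n_quad_nodes: int = 15
    proposal_df: float = 20.0
    proposal_scale: float = 1.05

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def kept_per_chain(self) -> int:
        return len(range(self.burn_in, self.n_iterations, self.thinning))


# ---------------------------------------------------------------------------
# posterior draws container


@dataclass
class MarkerDraws:
    """Kept MCMC draws for one marker's parameters.

    ``values`` has one column per entry of ``columns`` (the fixed effects in
    covariate order, then intercept_mean, then intercept_sd on its natural
    scale)."""

    columns: tuple[str, ...]
    values: np.ndarray  # (n_draws, n_params)
    chain: np.ndarray  # (n_draws,) chain ids
    iteration: np.ndarray  # (n_draws,) iteration index within chain
    acceptance: tuple[float, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


@dataclass
class PosteriorDraws:
    group: str
    spec: MGLMMSpec
    markers: dict[str, MarkerDraws] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.markers.values())).n_draws

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, md in self.markers.items():
            for c, col in enumerate(md.columns):
                rows.append(
                    pd.DataFrame(
                        {
                            "group": self.group,
                            "marker": name,
                            "parameter": col,
                            "chain": md.chain,
                            "iteration": md.iteration,
                            "value": md.values[:, c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# design and marginal likelihood


def build_marker_arrays(
    individuals: list[IndividualRecord],
    mspec: MarkerSpec,
    grid: OccasionGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Response (n, J) and fixed-effect design (n, J, p) for one marker."""
    n, J = len(individuals), grid.n_occasions
    r = MARKER_ORDER.index(mspec.name)
    Y = np.array([np.asarray(ind.measures)[:, r] for ind in individuals], dtype=float)
    cols = []
    for cov in mspec.covariates:
        if cov == "male":
            v = np.array([1.0 if ind.sex == "male" else 0.0 for ind in individuals])
            cols.append(np.repeat(v[:, None], J, axis=1))
        elif cov == "urban":
            v = np.array([1.0 if ind.region == "urban" else 0.0 for ind in individuals])
            cols.append(np.repeat(v[:, None], J, axis=1))
        elif cov == "age":
            cols.append(np.repeat(grid.covariate_ages[None, :], n, axis=0))
    X = np.stack(cols, axis=-1) if cols else np.zeros((n, J, 0))
    return Y, X


class MarginalLikelihood:
    """Random-intercept-marginalized log-likelihood for one marker.

    The intercept is integrated out with adaptive Gauss-Hermite quadrature
    (nodes centered at each unit's conditional mode; see ``_agq``), which
    stays accurate even when a unit's history makes its intercept posterior
    much narrower than the random-effects distribution. Sufficient
    statistics keep evaluations cheap: Poisson units reduce to scalar
    (count sum, rate-multiplier sum); Bernoulli units sharing a covariate
    pattern and event count share their integral, so individuals are
    collapsed to at most patterns x (J + 1) groups.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, family: str, n_nodes: int = 31):
        self.Y = np.asarray(Y, dtype=float)
        self.family = family
        n, J = self.Y.shape if self.Y.ndim == 2 else (0, 0)
        if n and X.shape[2] == 0:  # intercept-only marker: one shared pattern
            self.pat_X = np.zeros((1, J, 0))
            self.pat_idx = np.zeros(n, dtype=int)
        elif n:
            flat = np.ascontiguousarray(X, dtype=float).reshape(n, -1)
            self.pat_X, self.pat_idx = np.unique(flat, axis=0, return_inverse=True)
            self.pat_X = self.pat_X.reshape(-1, X.shape[1], X.shape[2])
        else:
            self.pat_X = np.zeros((0,) + np.asarray(X).shape[1:])
            self.pat_idx = np.zeros(0, dtype=int)
        self.s = self.Y.sum(axis=1) if n else np.zeros(0)
        if family == "bernoulli_logit":
            if n and not np.isin(self.Y, (0.0, 1.0)).all():
                raise ValueError("Bernoulli marker has non-binary values")
            self.const = np.zeros(n)
        elif family == "poisson_log":
            if n and (np.any(self.Y < 0) or np.any(self.Y != np.round(self.Y))):
                raise ValueError("Poisson marker has negative or non-integer values")
            self.const = -gammaln(self.Y + 1.0).sum(axis=1) if n else np.zeros(0)
        else:
            raise ValueError(f"unknown family {family!r}")
        # individuals with the same covariate pattern and count total share
        # their marginal integral
        if n:
            key = self.pat_idx * (int(self.s.max()) + 2) + self.s.astype(int)
            _, first, self.grp_idx = np.unique(key, return_index=True, return_inverse=True)
            self.g_pat = self.pat_idx[first]
            self.g_s = self.s[first]
            self.g_count = np.bincount(self.grp_idx).astype(float)
            self.ysum_pat = np.zeros(self.pat_X.shape[:2])  # (P, J)
            np.add.at(self.ysum_pat, self.pat_idx, self.Y)
        else:
            self.g_pat = np.zeros(0, dtype=int)
            self.g_s = np.zeros(0)
            self.g_count = np.zeros(0)
            self.ysum_pat = np.zeros((0, 0))
        self.x, self.logw = _agq.hermite_rule(n_nodes)
        self.n = n

    def _group_logA(self, mu: np.ndarray, mean, sd) -> np.ndarray:
        """Per-group marginal integral; mu is (..., P, J)."""
        mu_g = mu[..., self.g_pat, :]
        if self.family == "bernoulli_logit":
            logA, _, _ = _agq.bernoulli_marginal(
                mu_g, self.g_s, mean, sd, self.x, self.logw
            )
        else:
            with np.errstate(over="ignore"):
                S_g = np.exp(mu_g).sum(axis=-1)
            logA, _, _ = _agq.poisson_marginal(
                S_g, self.g_s, mean, sd, self.x, self.logw
            )
        return logA

    def per_individual(self, alpha: np.ndarray, mean: float, sd: float) -> np.ndarray:
        """Marginal log-likelihood contribution of each individual."""
        if self.n == 0:
            return np.zeros(0)
        if sd <= 0:
            raise ValueError("intercept SD must be positive")
        alpha = np.asarray(alpha, dtype=float)
        mu = self.pat_X @ alpha  # (P, J)
        ymu = np.einsum("nj,nj->n", self.Y, mu[self.pat_idx])
        logA = self._group_logA(mu, mean, sd)
        return ymu + self.const + logA[self.grp_idx]

    def batch_total(
        self, alpha: np.ndarray, mean: np.ndarray, sd: np.ndarray,
        chunk: int = 256,
    ) -> np.ndarray:
        """Total marginal log-likelihood for a batch of parameter vectors.

        alpha (B, p), mean (B,), sd (B,): one vectorized pass instead of B
        scalar evaluations; used by the sampler and the deviance."""
        B = alpha.shape[0]
        if self.n == 0:
            return np.zeros(B)
        out = np.empty(B)
        const_sum = float(self.const.sum())
        for lo in range(0, B, chunk):
            hi = min(lo + chunk, B)
            a = alpha[lo:hi]
            mu = np.einsum("pjq,bq->bpj", self.pat_X, a)  # (b, P, J)
            ymu_tot = np.einsum("pj,bpj->b", self.ysum_pat, mu)
            logA = self._group_logA(mu, mean[lo:hi, None], sd[lo:hi, None])
            out[lo:hi] = ymu_tot + const_sum + logA @ self.g_count
        return out

    def total(self, alpha: np.ndarray, mean: float, sd: float) -> float:
        return float(self.per_individual(alpha, mean, sd).sum())


def linear_predictor(fixed: np.ndarray, covariates: np.ndarray, intercept_b: float) -> float:
    """x'alpha + b; the mean response is the inverse link applied to this."""
    fixed = np.asarray(fixed, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if fixed.shape != covariates.shape:
        raise ValueError("fixed effects and covariates must have matching lengths")
    return float(fixed @ covariates + intercept_b)


def mean_response(lp: float, family: str) -> float:
    if family == "bernoulli_logit":
        return float(expit(lp))
    if family == "poisson_log":
        return float(np.exp(lp))
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# posterior, Laplace approximation, independence sampler


class MarkerPosterior:
    """Unnormalized log posterior over theta = (alpha..., mean, log_sd)."""

    def __init__(self, lik: MarginalLikelihood, spec: MGLMMSpec, n_fixed: int):
        self.lik = lik
        self.spec = spec
        self.p = n_fixed
        self.dim = n_fixed + 2

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        alpha, mean, log_sd = theta[: self.p], theta[self.p], theta[self.p + 1]
        if not np.all(np.isfinite(theta)) or abs(log_sd) > 12:
            return -np.inf
        sd = np.exp(log_sd)
        lp = (
            -0.5 * float(alpha @ alpha) / self.spec.prior_fixed_sd**2
            - 0.5 * mean**2 / self.spec.prior_intercept_mean_sd**2
            - 0.5 * sd**2 / self.spec.prior_intercept_sd_scale**2
            + log_sd  # Jacobian of the log transform
        )
        ll = self.lik.total(alpha, mean, sd)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    def batch(self, thetas: np.ndarray) -> np.ndarray:
        """Vectorized log posterior over rows of ``thetas``; -inf where invalid."""
        thetas = np.asarray(thetas, dtype=float)
        alpha = thetas[:, : self.p]
        mean = thetas[:, self.p]
        log_sd = thetas[:, self.p + 1]
        ok = np.all(np.isfinite(thetas), axis=1) & (np.abs(log_sd) <= 12)
        safe = np.where(ok[:, None], thetas, 0.0)
        alpha, mean, log_sd = safe[:, : self.p], safe[:, self.p], safe[:, self.p + 1]
        sd = np.exp(log_sd)
        lp = (
            -0.5 * np.einsum("bp,bp->b", alpha, alpha) / self.spec.prior_fixed_sd**2
            - 0.5 * mean**2 / self.spec.prior_intercept_mean_sd**2
            - 0.5 * sd**2 / self.spec.prior_intercept_sd_scale**2
            + log_sd
        )
        ll = self.lik.batch_total(alpha, mean, sd)
        out = lp + ll
        out[~ok | ~np.isfinite(out)] = -np.inf
        return out


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.zeros((d, d))
    hs = h * (1.0 + np.abs(x))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = hs[i]
            ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def _laplace(logpost, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a positive-definite covariance from -H^{-1}."""
    neg = lambda t: -logpost(t)
    res = optimize.minimize(neg, x0, method="BFGS", options={"maxiter": 500})
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"maxiter": 2000})
        res = optimize.minimize(neg, res.x, method="BFGS", options={"maxiter": 200})
    mode = res.x
    H = _num_hessian(neg, mode)
    evals, evecs = np.linalg.eigh(H)
    evals = np.clip(evals, 1e-8, None)  # guard flat/indefinite directions
    cov = (evecs / evals) @ evecs.T
    return mode, cov


def _run_independence_chain(
    logpost_batch, center: np.ndarray, chol: np.ndarray, df: float,
    n_iterations: int, rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Independence Metropolis-Hastings with a multivariate-t proposal.

    All proposals are drawn and scored up front (they do not depend on the
    chain state), so the posterior is evaluated in one vectorized batch; the
    accept/reject recursion is then a cheap scalar scan."""
    d = center.size
    n_draw = n_iterations + 1  # first draw initializes the chain
    z = rng.standard_normal((n_draw, d))
    u = rng.chisquare(df, n_draw)
    devs = (z @ chol.T) * np.sqrt(df / u)[:, None]
    props = center[None, :] + devs
    zz = np.linalg.solve(chol, devs.T)
    lq = -0.5 * (df + d) * np.log1p(np.einsum("db,db->b", zz, zz) / df)
    lp = logpost_batch(props)
    log_u = np.log(rng.random(n_iterations))

    cur = 0
    while cur < n_draw and not np.isfinite(lp[cur]):
        cur += 1
    if cur == n_draw:
        raise RuntimeError("no finite-posterior proposal found; check the data/model")
    out = np.empty((n_iterations, d))
    accepted = 0
    w_cur = lp[cur] - lq[cur]
    for it in range(n_iterations):
        k = it + 1
        if np.isfinite(lp[k]) and log_u[it] < (lp[k] - lq[k]) - w_cur:
            cur = k
            w_cur = lp[k] - lq[k]
            accepted += 1
        out[it] = props[cur]
    return out, accepted / n_iterations


def _initial_theta(Y: np.ndarray, family: str, p: int) -> np.ndarray:
    ybar = float(np.mean(Y)) if Y.size else 0.5
    if family == "bernoulli_logit":
        mean0 = float(np.log((ybar + 0.01) / (1 - ybar + 0.01)))
    else:
        mean0 = float(np.log(ybar + 0.05))
    return np.concatenate([np.zeros(p), [mean0, np.log(0.5)]])


def fit_marker(
    Y: np.ndarray,
    X: np.ndarray,
    mspec: MarkerSpec,
    spec: MGLMMSpec,
    mcmc: McmcConfig,
    seed_seq: np.random.SeedSequence,
) -> MarkerDraws:
    """Fit one marker's random-intercept GLMM by independence MH."""
    p = X.shape[2]
    lik = MarginalLikelihood(Y, X, mspec.family, mcmc.n_quad_nodes)
    logpost = MarkerPosterior(lik, spec, p)
    mode, cov = _laplace(logpost, _initial_theta(Y, mspec.family, p))
    chol = np.linalg.cholesky(cov) * mcmc.proposal_scale

    n_keep_iters = mcmc.n_iterations - mcmc.burn_in
    keep = np.arange(0, n_keep_iters, mcmc.thinning)
    values, chains, iters, acc = [], [], [], []
    for c, child in enumerate(seed_seq.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        # burn-in stage doubles as proposal adaptation: the Laplace proposal
        # is replaced by a t built on the burn-in draws' mean/covariance
        # (adaptation stops before any kept draw, so the kept chain is a
        # fixed-kernel independence sampler)
        center, spread = mode, chol
        if mcmc.burn_in > 0:
            warm, _ = _run_independence_chain(
                logpost.batch, center, spread, mcmc.proposal_df, mcmc.burn_in, rng
            )
            emp_mean = warm.mean(axis=0)
            emp_cov = np.cov(warm.T) + 1e-10 * np.eye(warm.shape[1])
            try:
                refined = np.linalg.cholesky(emp_cov) * mcmc.proposal_scale
                center, spread = emp_mean, refined
            except np.linalg.LinAlgError:
                pass  # degenerate burn-in: keep the Laplace proposal
        draws, a = _run_independence_chain(
            logpost.batch, center, spread, mcmc.proposal_df, n_keep_iters, rng
        )
        kept = draws[keep]
        values.append(kept)
        chains.append(np.full(kept.shape[0], c))
        iters.append(mcmc.burn_in + keep)
        acc.append(a)
        if a < 0.15:
            _log.warning(
                "marker %s chain %d: low independence-MH acceptance %.3f",
                mspec.name, c, a,
            )
    values = np.concatenate(values)
    values = np.column_stack([values[:, :-1], np.exp(values[:, -1])])  # sd scale
    return MarkerDraws(
        columns=tuple(mspec.covariates) + ("intercept_mean", "intercept_sd"),
        values=values,
        chain=np.concatenate(chains),
        iteration=np.concatenate(iters),
        acceptance=tuple(acc),
    )


def fit_mglmm(
    group_data: list[IndividualRecord],
    spec: MGLMMSpec = JA_UTILIZATION_MODEL,
    mcmc: McmcConfig = McmcConfig(),
    grid: OccasionGrid = DEFAULT_GRID,
) -> PosteriorDraws:
    """Fit the group's MGLMM (every marker in ``spec``) by MCMC.

    ``group_data`` must be the individuals of a single group; the returned
    draws are reproducible given ``mcmc.seed``.
    """
    if len(group_data) < 2:
        raise ValueError("need at least two individuals to fit a group model")
    groups = {ind.group for ind in group_data}
    if len(groups) != 1:
        raise ValueError(f"group_data mixes groups {sorted(groups)}")
    group = groups.pop()

    root = np.random.SeedSequence(mcmc.seed)
    marker_seqs = root.spawn(len(spec.markers))
    draws = PosteriorDraws(group=group, spec=spec)
    for mspec, seq in zip(spec.markers, marker_seqs):
        Y, X = build_marker_arrays(group_data, mspec, grid)
        if np.all(Y == Y.flat[0]):
            raise ValueError(f"marker {mspec.name} is constant in this group")
        draws.markers[mspec.name] = fit_marker(Y, X, mspec, spec, mcmc, seq)
    return draws


# ---------------------------------------------------------------------------
# convergence diagnostics


def psrf(chains: np.ndarray) -> tuple[float, float]:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_iterations). Returns the point estimate and
    the 97.5% upper confidence limit, with the degrees-of-freedom adjustment
    of the original formulation.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("psrf needs >= 2 chains of equal length")
    m, n = a.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    s2 = a.var(axis=1, ddof=1)
    xbar = a.mean(axis=1)
    W = float(s2.mean())
    B = float(n * xbar.var(ddof=1))
    if W <= 0:
        return 1.0, 1.0  # constant identical chains
    muhat = float(xbar.mean())
    var_w = float(s2.var(ddof=1)) / m
    var_b = 2.0 * B * B / (m - 1)
    cov_s2_x2 = float(np.cov(s2, xbar**2, ddof=1)[0, 1])
    cov_s2_x = float(np.cov(s2, xbar, ddof=1)[0, 1])
    cov_wb = (n / m) * (cov_s2_x2 - 2.0 * muhat * cov_s2_x)
    sigma2 = ((n - 1) * W + B) / n
    V = sigma2 + B / (m * n)
    var_V = (
        (n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b + 2 * (n - 1) * (1 + 1 / m) * cov_wb
    ) / n**2
    df_V = 2 * V**2 / var_V if var_V > 0 else np.inf
    df_adj = (df_V + 3) / (df_V + 1) if np.isfinite(df_V) else 1.0
    r2_fixed = (n - 1) / n
    r2_random = (1 + 1 / m) / n * B / W
    point = float(np.sqrt(df_adj * (r2_fixed + r2_random)))
    w_df = 2 * W**2 / var_w if var_w > 0 else np.inf
    if np.isfinite(w_df):
        fq = float(stats.f.ppf(0.975, m - 1, w_df))
    else:
        fq = float(stats.chi2.ppf(0.975, m - 1) / (m - 1))
    upper = float(np.sqrt(df_adj * (r2_fixed + fq * r2_random)))
    return point, upper


def autocorrelation(series: np.ndarray, lags: tuple[int, ...] = (1, 10, 50)) -> dict[int, float]:
    """Sample autocorrelation of one chain at the given lags (nan if too short)."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    out = {}
    for lag in lags:
        if lag >= len(x) or denom == 0:
            out[lag] = float("nan")
        else:
            out[lag] = float(x[:-lag] @ x[lag:]) / denom
    return out


def psrf_converged(point_upper: tuple[float, float], threshold: float = 1.02) -> bool:
    """Operational convergence flag: PSRF upper confidence limit below 1.02."""
    return point_upper[1] < threshold


def convergence_table(draws: PosteriorDraws, split: bool = True):
    """PSRF point/upper/flag for every parameter of every marker.

    By default each chain is split in half before the diagnostic (the
    standard refinement: it also detects within-chain drift and makes the
    upper confidence limit far less noisy than the raw two-chain version)."""
    import pandas as pd

    rows = []
    for name, md in draws.markers.items():
        chain_ids = np.unique(md.chain)
        for c, col in enumerate(md.columns):
            per_chain = [md.values[md.chain == cid, c] for cid in chain_ids]
            if split:
                halves = []
                for x in per_chain:
                    h = len(x) // 2
                    halves += [x[:h], x[h : 2 * h]]
                per_chain = halves
            length = min(len(x) for x in per_chain)
            arr = np.stack([x[:length] for x in per_chain])
            point, upper = psrf(arr)
            rows.append(
                {
                    "marker": name,
                    "parameter": col,
                    "psrf": point,
                    "psrf_upper": upper,
                    "converged": upper < 1.02,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# penalized expected deviance


def penalized_expected_deviance(
    draws: PosteriorDraws,
    group_data: list[IndividualRecord],
    grid: OccasionGrid = DEFAULT_GRID,
    n_quad_nodes: int = 31,
    max_draws: int = 1000,
) -> float:
    """Expected deviance plus an optimism penalty; lower is better fit.

    The deviance is -2 times the random-intercept-marginalized log
    likelihood. The optimism penalty is twice the effective number of
    parameters p_D = E[D] - D(posterior mean); with a single chain it falls
    back to the DIC-style penalty p_D alone (logged).
    """
    dbar_total = 0.0
    p_d_total = 0.0
    n_chains = 1
    for mspec in draws.spec.markers:
        md = draws.markers[mspec.name]
        n_chains = max(n_chains, np.unique(md.chain).size)
        Y, X = build_marker_arrays(group_data, mspec, grid)
        lik = MarginalLikelihood(Y, X, mspec.family, n_quad_nodes)
        p = len(mspec.covariates)
        idx = np.arange(md.n_draws)
        if md.n_draws > max_draws:
            idx = np.linspace(0, md.n_draws - 1, max_draws).astype(int)
        devs = -2.0 * lik.batch_total(
            md.values[idx, :p], md.values[idx, p], md.values[idx, p + 1]
        )
        dbar = float(devs.mean())
        theta_bar = md.values[idx].mean(axis=0)
        dhat = -2.0 * lik.total(theta_bar[:p], theta_bar[p], theta_bar[p + 1])
        dbar_total += dbar
        p_d_total += dbar - dhat
    if n_chains >= 2:
        penalty = 2.0 * p_d_total
    else:
        _log.warning(
            "penalized_expected_deviance: single chain; using DIC-style penalty p_D"
        )
        penalty = p_d_total
    return dbar_total + penalty
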