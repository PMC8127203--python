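import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from dynacase import (
    FULL_MODEL,
    GeneratorConfig,
    JA_UTILIZATION_MODEL,
    McmcConfig,
    MGLMMSpec,
    MarkerSpec,
    fit_mglmm,
    generate_cohort,
    linear_predictor,
    mean_response,
    penalized_expected_deviance,
    psrf,
)
from dynacase import mglmm as mg

AGES = np.r_[1.0, np.arange(2.0, 16.0)]


def _make_design(n, J, rng):
    return np.stack(
        [
            np.repeat(rng.integers(0, 2, n)[:, None], J, 1).astype(float),
            np.repeat(rng.integers(0, 2, n)[:, None], J, 1).astype(float),
            np.tile(AGES[:J], (n, 1)),
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# linear predictor


def test_linear_predictor_identities():
    assert mean_response(linear_predictor(np.zeros(3), np.ones(3), 0.0),
                         "bernoulli_logit") == pytest.approx(0.5)
    # intercept-only Poisson: mean is exp of the intercept
    assert mean_response(linear_predictor(np.zeros(0), np.zeros(0), 1.62),
                         "poisson_log") == pytest.approx(np.exp(1.62))
    lp0 = linear_predictor(np.array([0.2, -0.1]), np.array([1.0, 3.0]), 0.5)
    lp1 = linear_predictor(np.array([0.2, -0.1]), np.array([1.0, 3.0]), 0.5 + 2.0)
    assert lp1 - lp0 == pytest.approx(2.0)
    with pytest.raises(ValueError):
        linear_predictor(np.zeros(2), np.zeros(3), 0.0)


# ---------------------------------------------------------------------------
# marginal likelihood vs independent closed-form integration


@pytest.mark.parametrize("family", ["bernoulli_logit", "poisson_log"])
def test_marginal_likelihood_matches_grid_integration(family):
    """Per-individual marginalized log-likelihood agrees with dense-grid
    integration of the closed-form scipy pmf against the normal density."""
    rng = np.random.default_rng(7)
    n, J = 6, 15
    X = _make_design(n, J, rng)
    if family == "bernoulli_logit":
        alpha, E, SD = np.array([-0.59, -0.24, 0.21]), -1.77, 1.6
    else:
        alpha, E, SD = np.array([0.03, -0.50, -0.11]), 1.62, 0.94
    b = rng.normal(E, SD, n)
    eta = X @ alpha + b[:, None]
    if family == "bernoulli_logit":
        Y = (rng.random((n, J)) < 1 / (1 + np.exp(-eta))).astype(float)
    else:
        Y = rng.poisson(np.exp(eta)).astype(float)
    lik = mg.MarginalLikelihood(Y, X, family, 31)
    mine = lik.per_individual(alpha, E, SD)

    grid = np.linspace(E - 14 * SD, E + 14 * SD, 300001)
    for i in range(n):
        lin = (X[i] @ alpha)[:, None] + grid[None, :]
        if family == "bernoulli_logit":
            ll = stats.bernoulli.logpmf(Y[i][:, None], 1 / (1 + np.exp(-lin))).sum(0)
        else:
            ll = stats.poisson.logpmf(Y[i][:, None], np.exp(lin)).sum(0)
        ref = logsumexp(ll + stats.norm.logpdf(grid, E, SD)) + np.log(grid[1] - grid[0])
        assert mine[i] == pytest.approx(ref, abs=1e-8)


def test_batch_total_matches_scalar_path():
    rng = np.random.default_rng(1)
    n, J = 40, 15
    X = _make_design(n, J, rng)
    Y = rng.poisson(2.0, (n, J)).astype(float)
    lik = mg.MarginalLikelihood(Y, X, "poisson_log", 15)
    thetas = np.column_stack(
        [rng.normal(0, 0.3, (5, 3)), rng.normal(0.5, 0.2, 5), rng.uniform(0.4, 1.2, 5)]
    )
    batch = lik.batch_total(thetas[:, :3], thetas[:, 3], thetas[:, 4])
    scalar = [lik.total(t[:3], t[3], t[4]) for t in thetas]
    np.testing.assert_allclose(batch, scalar, rtol=1e-10)


# ---------------------------------------------------------------------------
# PSRF


def test_psrf_identical_chains_near_one():
    rng = np.random.default_rng(0)
    chain = rng.standard_normal(5000)
    point, upper = psrf(np.stack([chain, chain]))
    assert point == pytest.approx(1.0, abs=0.01)
    assert upper == pytest.approx(1.0, abs=0.01)


def test_psrf_stationary_chains_converged():
    rng = np.random.default_rng(3)
    chains = rng.standard_normal((2, 10000))
    point, upper = psrf(chains)
    assert upper < 1.02


def test_psrf_divergent_chains_flagged():
    rng = np.random.default_rng(4)
    chains = np.stack([rng.standard_normal(2000), 10 + rng.standard_normal(2000)])
    point, upper = psrf(chains)
    assert point > 1.1 and upper > 1.1


def test_psrf_input_contracts():
    with pytest.raises(ValueError):
        psrf(np.zeros((1, 100)))
    with pytest.raises(ValueError):
        psrf(np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# fitting


def _tiny_mcmc(seed=0):
    return McmcConfig(n_iterations=800, burn_in=200, thinning=3, n_chains=2, seed=seed)


def test_fit_is_deterministic_given_seed():
    cohort = generate_cohort(GeneratorConfig(n_individuals=80, case_fraction=1.0, seed=2))
    a = fit_mglmm(cohort, JA_UTILIZATION_MODEL, _tiny_mcmc(5))
    b = fit_mglmm(cohort, JA_UTILIZATION_MODEL, _tiny_mcmc(5))
    np.testing.assert_array_equal(
        a.markers["ja_contact"].values, b.markers["ja_contact"].values
    )


def test_fit_input_contracts():
    cohort = generate_cohort(GeneratorConfig(n_individuals=30, seed=2))
    with pytest.raises(ValueError):
        fit_mglmm(cohort[:1], JA_UTILIZATION_MODEL, _tiny_mcmc())
    with pytest.raises(ValueError):
        fit_mglmm(cohort, JA_UTILIZATION_MODEL, _tiny_mcmc())  # mixed groups
    with pytest.raises(NotImplementedError):
        MGLMMSpec(markers=JA_UTILIZATION_MODEL.markers, n_mixture_components=2)


def test_draw_count_matches_chains_and_thinning():
    cohort = generate_cohort(GeneratorConfig(n_individuals=60, case_fraction=1.0, seed=3))
    mcmc = _tiny_mcmc(1)
    draws = fit_mglmm(cohort, JA_UTILIZATION_MODEL, mcmc)
    md = draws.markers["ja_contact"]
    assert md.n_draws == mcmc.n_chains * mcmc.kept_per_chain
    assert np.all(md.column("intercept_sd") > 0)


def test_posterior_equals_prior_with_no_data():
    """No-observation limit: the sampled posterior reproduces the prior
    (normal fixed effects and intercept mean, half-normal intercept SD)."""
    spec = JA_UTILIZATION_MODEL
    lik = mg.MarginalLikelihood(np.zeros((0, 15)), np.zeros((0, 15, 1)), "bernoulli_logit")
    post = mg.MarkerPosterior(lik, spec, 1)
    mode, cov = mg._laplace(post, np.array([0.0, 0.0, np.log(3.0)]))
    rng = np.random.default_rng(8)
    chol = np.linalg.cholesky(cov) * 1.3
    draws, acc = mg._run_independence_chain(post.batch, mode, chol, 8.0, 20000, rng)
    kept = draws[2000:]
    assert acc > 0.2
    # fixed effect and intercept mean ~ N(0, 10^2)
    for col in (0, 1):
        assert abs(np.mean(kept[:, col])) < 1.0
        assert np.std(kept[:, col]) == pytest.approx(10.0, rel=0.15)
    # intercept SD ~ Half-Normal(5): median at 5*z_{0.75}
    sd = np.exp(kept[:, 2])
    assert np.median(sd) == pytest.approx(5 * stats.norm.ppf(0.75), rel=0.2)


def test_posterior_contraction_with_sample_size():
    """Doubling the group size shrinks the average CrI width roughly by
    sqrt(2) (checked loosely to allow Monte-Carlo noise)."""
    widths = {}
    for n in (150, 600):
        cohort = generate_cohort(
            GeneratorConfig(n_individuals=n, case_fraction=1.0, seed=31)
        )
        draws = fit_mglmm(cohort, JA_UTILIZATION_MODEL, _tiny_mcmc(2))
        md = draws.markers["ja_contact"]
        lo, hi = np.quantile(md.values, [0.025, 0.975], axis=0)
        widths[n] = np.mean(hi - lo)
    ratio = widths[150] / widths[600]
    assert 1.4 < ratio < 3.5  # ideal 2 for a 4x size increase


# ---------------------------------------------------------------------------
# penalized expected deviance


def test_ped_prefers_true_covariate_structure_and_is_stable():
    """On data generated with real covariate effects the saturated marker
    model attains lower PED than the intercept-only model, and PED is stable
    across sampler seeds."""
    cohort = generate_cohort(
        GeneratorConfig(n_individuals=250, case_fraction=1.0, seed=13)
    )
    saturated = JA_UTILIZATION_MODEL
    null_spec = MGLMMSpec(
        markers=(MarkerSpec("ja_contact", "bernoulli_logit", ()),)
    )
    mcmc = McmcConfig(n_iterations=1200, burn_in=300, thinning=3, n_chains=2, seed=5)
    fit_sat = fit_mglmm(cohort, saturated, mcmc)
    fit_null = fit_mglmm(cohort, null_spec, mcmc)
    ped_sat = penalized_expected_deviance(fit_sat, cohort)
    ped_null = penalized_expected_deviance(fit_null, cohort)
    assert ped_sat < ped_null

    fit_sat2 = fit_mglmm(cohort, saturated,
                         McmcConfig(n_iterations=1200, burn_in=300, thinning=3,
                                    n_chains=2, seed=99))
    ped_sat2 = penalized_expected_deviance(fit_sat2, cohort)
    assert abs(ped_sat - ped_sat2) < max(10.0, 0.01 * abs(ped_sat))
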