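import numpy as np
import pytest

from dynacase import (
    FULL_MODEL,
    GeneratorConfig,
    MarkerDraws,
    PosteriorDraws,
    generate_cohort,
)
from dynacase.simdata import MarkerParams, default_case_params, default_control_params


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated two-group cohort for pipeline tests."""
    cfg = GeneratorConfig(n_individuals=150, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_individuals=150, seed=42)


def make_posterior_draws(
    group: str,
    params: dict[str, MarkerParams] | None = None,
    spec=FULL_MODEL,
    n_draws: int = 60,
    jitter: float = 0.02,
    seed: int = 0,
) -> PosteriorDraws:
    """Synthetic PosteriorDraws: tight draws around given generating values.

    Stands in for an MCMC fit in tests that exercise the discriminant and
    classification layers without paying for sampling.
    """
    if params is None:
        params = default_case_params() if group == "case" else default_control_params()
    rng = np.random.default_rng(seed)
    draws = PosteriorDraws(group=group, spec=spec)
    for mspec in spec.markers:
        mp = params[mspec.name]
        truth = {
            "male": mp.male,
            "urban": mp.urban,
            "age": mp.age,
            "intercept_mean": mp.intercept_mean,
            "intercept_sd": mp.intercept_sd,
        }
        cols = tuple(mspec.covariates) + ("intercept_mean", "intercept_sd")
        center = np.array([truth[c] for c in cols])
        values = center[None, :] + jitter * rng.standard_normal((n_draws, len(cols)))
        values[:, -1] = np.abs(values[:, -1])  # SD stays positive
        half = n_draws // 2
        draws.markers[mspec.name] = MarkerDraws(
            columns=cols,
            values=values,
            chain=np.repeat([0, 1], [half, n_draws - half]),
            iteration=np.concatenate([np.arange(half), np.arange(n_draws - half)]),
        )
    return draws
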