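import numpy as np
import pytest

from lscggm.core import CRFParameters, Dataset, SufficientStats, suff_stats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=300, m=2, p=3):
    return Dataset(y_z=rng.standard_normal((n, m)), y_x=rng.standard_normal((n, p)))


def random_feasible_params(rng, p=3, m=2, latent_scale=0.3):
    """Random parameters with S_X - L_X strictly PD and L_X PSD."""
    a = rng.standard_normal((p, max(1, p // 2))) * latent_scale
    l_x = a @ a.T
    b = rng.standard_normal((p, p)) * 0.3
    s_x = l_x + b @ b.T + np.eye(p)
    return CRFParameters(
        s_x=s_x,
        l_x=l_x,
        s_zx=0.3 * rng.standard_normal((m, p)),
        l_zx=0.1 * rng.standard_normal((m, p)),
    )


def model_implied_stats(params: CRFParameters, n=1000) -> SufficientStats:
    """Noiseless 'infinite data' second moments implied by the parameters
    with standard-normal inputs: the population moments of the model, so the
    unpenalized MLE equals the parameters exactly."""
    from lscggm.core import conditional_distribution

    law = conditional_distribution(params)
    m = params.m
    sigma_z = np.eye(m)
    sigma_zx = sigma_z @ law.coefficient_map
    sigma_x = law.conditional_covariance + law.coefficient_map.T @ sigma_zx
    return SufficientStats(sigma_z=sigma_z, sigma_x=sigma_x, sigma_zx=sigma_zx, n=n)


@pytest.fixture
def small_stats(rng):
    return suff_stats(random_dataset(rng))
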