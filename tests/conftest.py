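"""Shared fixtures: small synthetic right-censored Weibull MPR datasets."""

import numpy as np
import pytest

from penmpr import MprParameters, SurvivalDataset


def make_weibull_dataset(
    n=30,
    p=2,
    q=2,
    seed=0,
    censor_frac=0.3,
    beta=None,
    alpha=None,
    standardize=True,
):
    """Dataset drawn from a Weibull MPR truth with uniform censoring.

    Small, quick, and independent of the package's own study generator so it
    can back oracle checks of the likelihood machinery.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((n, q))
    if beta is None:
        beta = np.concatenate([[-0.5], 0.4 * np.ones(p)])
    if alpha is None:
        alpha = np.concatenate([[0.2], -0.3 * np.ones(q)])
    tau = np.exp(np.column_stack([np.ones(n), X]) @ beta)
    gam = np.exp(np.column_stack([np.ones(n), Z]) @ alpha)
    t_event = (-np.log(rng.uniform(size=n)) / tau) ** (1.0 / gam)
    if censor_frac > 0:
        c = rng.uniform(0, np.quantile(t_event, 1 - censor_frac / 2), size=n)
        times = np.minimum(t_event, c)
        events = (t_event <= c).astype(float)
    else:
        times, events = t_event, np.ones(n)
    return SurvivalDataset.from_covariates(
        times, events, X, Z, standardize=standardize
    )


@pytest.fixture
def small_dataset():
    return make_weibull_dataset(n=30, seed=12)


@pytest.fixture
def medium_dataset():
    return make_weibull_dataset(n=300, seed=5)


@pytest.fixture
def random_params():
    rng = np.random.default_rng(3)
    return MprParameters(beta=rng.normal(0, 0.3, 3), alpha=rng.normal(0, 0.2, 3))
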