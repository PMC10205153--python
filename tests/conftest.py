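import numpy as np
import pandas as pd
import pytest

from erpseq.model import ModelSpec, PriorSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def conjugate_data(rng):
    """Known-variance Gaussian regression with analytic posterior and ML."""
    n = 50
    sigma = 1.5
    x = rng.standard_normal(n)
    y = 1.0 + 0.4 * x + rng.normal(0, sigma, n)
    table = pd.DataFrame({"amplitude": y, "x": x})
    spec = ModelSpec(
        "amplitude",
        ["x"],
        random_subject=[],
        random_item=False,
        priors={
            "intercept": PriorSpec("normal", 0.0, 5.0),
            "x": PriorSpec("normal", 0.0, 1.0),
        },
        sigma_residual_fixed=sigma,
    )
    return table, spec, sigma


def analytic_log_ml(y, X, S0, sigma):
    """Closed-form marginal likelihood of a conjugate Gaussian regression."""
    from scipy.stats import multivariate_normal

    V = sigma**2 * np.eye(len(y)) + X @ S0 @ X.T
    return float(multivariate_normal(mean=np.zeros(len(y)), cov=V).logpdf(y))
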