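import numpy as np
import pytest

from pea.pql import NullModelFit


@pytest.fixture
def synthetic_fit():
    """Factory for a lightweight null-model state with a random PD working
    covariance, for exercising the score statistic without a model fit."""

    def make(rng: np.random.Generator, N: int) -> NullModelFit:
        A = rng.standard_normal((N, N))
        V = A @ A.T + N * np.eye(N)
        resid = rng.standard_normal(N)
        return NullModelFit(
            beta_C=np.zeros(1),
            alpha=np.zeros(N),
            tau=float(rng.uniform(0.1, 2.0)),
            gamma=np.full(N, 0.5),
            d=np.full(N, 0.25),
            y_work=resid.copy(),
            Vinv=np.linalg.inv(V),
            resid=resid,
            converged=True,
            n_iter=1,
        )

    return make
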