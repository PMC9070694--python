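import numpy as np
import pytest

from hmcscatter.likelihood import CallableTarget


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_target(cov):
    """Analytic multivariate-normal target with exact gradient."""
    cov = np.atleast_2d(np.asarray(cov, float))
    prec = np.linalg.inv(cov)
    return CallableTarget(
        U=lambda z: 0.5 * float(z @ prec @ z),
        grad=lambda z: prec @ z,
    )


@pytest.fixture
def std_normal_1d():
    return CallableTarget(U=lambda z: 0.5 * float(z @ z), grad=lambda z: z)
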