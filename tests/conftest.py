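import numpy as np
import pytest

from temporalpc.core import TPCModel
from temporalpc.state_space import StateSpaceModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state_space(rng, dx=3, du=1, dy=3, stable=True, f="linear"):
    """A random linear-Gaussian system, spectrally scaled to be stable."""
    A = rng.standard_normal((dx, dx))
    if stable:
        A *= 0.9 / max(abs(np.linalg.eigvals(A)))
    return StateSpaceModel(
        A=A,
        B=rng.standard_normal((dx, du)),
        C=rng.standard_normal((dy, dx)),
        Sigma_x=np.eye(dx),
        Sigma_y=np.eye(dy),
        f=f,
    )


def random_tpc(rng, dx=3, du=1, dy=3, f="linear", diag_precisions=False):
    """A random tPC network with finite carried state."""
    Pi_x = np.diag(rng.uniform(0.5, 2.0, dx)) if diag_precisions else None
    Pi_y = np.diag(rng.uniform(0.5, 2.0, dy)) if diag_precisions else None
    return TPCModel(
        A=rng.standard_normal((dx, dx)) * 0.5,
        B=rng.standard_normal((dx, du)),
        C=rng.standard_normal((dy, dx)),
        Pi_x=Pi_x,
        Pi_y=Pi_y,
        f=f,
        x_prev=rng.standard_normal(dx),
    )
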