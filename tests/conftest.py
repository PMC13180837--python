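import numpy as np
import pytest

import geoexposure as gx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_graph(rng):
    coords = rng.uniform(0, 1, size=(6, 2))
    return gx.build_adjacency(coords, sigma=0.4, delta=1.5)


def build_linear_model(beta, tau: int = 2) -> gx.ModelState:
    """A network that computes exactly H_hat = E_t . beta (lag-0 linear map).

    Uses the ReLU decomposition x = relu(x) - relu(-x) across a doubled
    latent so the composition is linear for inputs of any sign; all other
    stages are disabled or zeroed.  Single outcome.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = beta.shape[0]
    d = 2 * p
    cfg = gx.ModelConfig(d=d, diffusion_depth=1, tau=tau, n_exposures=p,
                         n_outcomes=1, use_gpl=False, use_tam=False,
                         use_aci=False)
    m = gx.init_model(cfg, seed=0)
    for t in m.params.values():
        t.data[:] = 0.0
    eye = np.eye(p)
    m.params["conv1_W"].data[0] = np.hstack([eye, -eye])          # x -> (x+, x-)
    w2 = np.zeros((d, d))
    w2[0:p, 0:p] = eye
    w2[p:2 * p, 0:p] = -eye
    m.params["conv2_W"].data[0] = w2                              # -> (x, 0)
    m.params["alpha"].data[0] = 1.0
    m.params["out_W"].data[0:p, 0] = beta
    return m


@pytest.fixture
def linear_model():
    return build_linear_model
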