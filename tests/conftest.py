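import logging

import numpy as np
import pytest

from mrnet import SemSpec, attach_instruments


@pytest.fixture(autouse=True)
def _quiet_orientation_logs(caplog):
    # orientation conflict warnings are expected in recovery simulations
    logging.getLogger("mrnet.network").setLevel(logging.ERROR)
    yield


def make_chain(weights, alpha=None, noise=1.0):
    """Chain spec M0 -> M1 -> ... with given edge weights."""
    p = len(weights) + 1
    W = np.zeros((p, p))
    for i, w in enumerate(weights):
        W[i, i + 1] = w
    spec = SemSpec(
        entity_ids=[f"M{i}" for i in range(p)],
        adjacency=W,
        noise_sd=np.full(p, noise),
    )
    if alpha is not None:
        spec = attach_instruments(spec, alpha=alpha)
    return spec


@pytest.fixture
def chain3():
    """M0 -> M1 -> M2, every entity instrumented."""
    return make_chain([0.6, 0.6], alpha=0.6)
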