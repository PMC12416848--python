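import numpy as np
import pytest

from ecoassembly import ModelParams, build_community


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def two_mutualists():
    """Two species linked by a symmetric-support mutualism (weights 0.2)."""
    return build_community(
        species=[
            {"id": 0, "r": 0.1, "s": 1.0, "x": 0.1},
            {"id": 1, "r": 0.1, "s": 1.0, "x": 0.1},
        ],
        links=[{"source": 0, "target": 1, "type": "mutualism", "w_st": 0.2, "w_ts": 0.2}],
    )


@pytest.fixture
def three_chain():
    """Consumer chain: species 0 consumes 1, species 1 consumes 2."""
    return build_community(
        species=[
            {"id": 0, "r": 0.1, "s": 1.0, "x": 0.2},
            {"id": 1, "r": 0.1, "s": 1.0, "x": 0.3},
            {"id": 2, "r": 0.1, "s": 1.0, "x": 0.4},
        ],
        links=[
            {"source": 0, "target": 1, "type": "consumer_resource", "w_st": 0.15, "w_ts": 0.2},
            {"source": 1, "target": 2, "type": "consumer_resource", "w_st": 0.1, "w_ts": 0.1},
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
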