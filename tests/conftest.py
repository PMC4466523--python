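import numpy as np
import pytest

from nasemg.synthetic import ScenarioConfig, make_scenario


@pytest.fixture(scope="session")
def scenario8():
    """Mid-size reference scenario with a known piecewise-linear warp,
    shared (read-only) across test modules."""
    cfg = ScenarioConfig(
        n_utterances=8,
        seed=7,
        warp_params=[[0.0, 0.0], [4.0, 4.12], [12.0, 11.95]],
    )
    return make_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
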