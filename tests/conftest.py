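import numpy as np
import pytest

from omagkit import FlowSegment, phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_flow_spec(velocity_mm_s=0.5, seed=7, **overrides):
    """A compact velocimetry-protocol phantom with one vessel."""
    params = dict(
        depth_px=32,
        n_positions=12,
        seed=seed,
        flow_segments=[FlowSegment((4, 8), (6, 10), velocity_mm_s)],
    )
    params.update(overrides)
    return phantoms.PhantomSpec(**params)


@pytest.fixture
def flow_phantom():
    return phantoms.make_flow_phantom(small_flow_spec())
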