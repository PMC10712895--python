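import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chondrosim.core import (
    CHONDROCYTE,
    KIND_CODE,
    PERICHONDRIAL,
    ModelParams,
    Population,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_population(
    positions,
    proliferative=False,
    kinds=None,
    clone_ids=None,
    g1=3.0,
    g2=1000.0,
    activated=None,
    seed=0,
) -> Population:
    """Hand-built population for unit tests (divisions off by default)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pos)
    kinds_arr = (
        np.asarray(kinds, dtype=np.int8)
        if kinds is not None
        else np.full(n, KIND_CODE[CHONDROCYTE], dtype=np.int8)
    )
    counts = kinds_arr == KIND_CODE[CHONDROCYTE]
    return Population(
        positions=pos,
        clone_ids=np.asarray(clone_ids) if clone_ids is not None else np.arange(n),
        kinds=kinds_arr,
        g1=np.full(n, g1, dtype=float),
        g2=np.full(n, g2, dtype=float) if np.isscalar(g2) else np.asarray(g2, float),
        proliferative=np.full(n, proliferative, dtype=bool)
        if np.isscalar(proliferative)
        else np.asarray(proliferative, bool),
        activated=np.zeros(n, dtype=bool) if activated is None else np.asarray(activated, bool),
        counts=counts,
        rng=np.random.default_rng(seed),
    )
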