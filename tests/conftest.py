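import numpy as np
import pytest

from germsoma import ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


def random_viable_point(rng, params, interior=0.05, zero_regulation=False):
    """Random interior trait point whose resident population is viable."""
    from germsoma import TraitPoint, monomorphic_colony_components

    for _ in range(1000):
        draw = rng.uniform(interior, 1 - interior, size=4)
        if zero_regulation:
            draw[2:] = 0.0
        pt = TraitPoint(*draw)
        F, V = monomorphic_colony_components(*pt, params)
        if params.S * F > 1.05 and V > 0:
            return pt
    raise RuntimeError("could not sample a viable resident")
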