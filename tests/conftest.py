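import numpy as np
import pytest

from pcqm import PatternSpec, PointPattern, Window, generate_random


@pytest.fixture
def hectare() -> Window:
    """The 100 m x 100 m (1 ha) survey window used throughout."""
    return Window.from_size(100.0, 100.0)


@pytest.fixture
def dense_random(hectare) -> PointPattern:
    """A 5,000 stems/ha random stand, fixed seed."""
    return generate_random(PatternSpec("random", 5000, hectare, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210)
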