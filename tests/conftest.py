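import numpy as np
import pytest

from flowerweb import InteractionMatrix, SyntheticConfig, generate_web


@pytest.fixture
def tiny_web() -> InteractionMatrix:
    """2x2 web used for all hand-worked dependency examples."""
    return InteractionMatrix(("p1", "p2"), ("b1", "b2"), np.array([[3, 1], [0, 2]]))


@pytest.fixture
def one_link_web() -> InteractionMatrix:
    return InteractionMatrix(("p1",), ("b1",), np.array([[7]]))


@pytest.fixture
def random_webs() -> list[InteractionMatrix]:
    """A few seeded generator webs for property checks."""
    return [
        generate_web(SyntheticConfig(R=8, C=15, n_visits=400, seed=s))
        for s in (1, 2, 3)
    ]
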