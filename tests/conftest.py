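import numpy as np
import pytest

import lipidmix as lm


@pytest.fixture(scope="session")
def design16() -> lm.Design:
    """The built-in 16-run S-type design (15 modeling + 1 hold-out)."""
    return lm.builtin_design()


@pytest.fixture(scope="session")
def bounds4() -> lm.ComponentBounds:
    return lm.builtin_bounds()


@pytest.fixture(scope="session")
def truths() -> dict[str, lm.GroundTruth]:
    return lm.builtin_models()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_mixture_design(rng: np.random.Generator, n: int, q: int) -> lm.Design:
    """Uniform simplex design helper for property tests."""
    x = rng.dirichlet(np.ones(q), size=n)
    return lm.Design(x, tuple(f"c{i}" for i in range(q)))
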