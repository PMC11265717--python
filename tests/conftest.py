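import numpy as np
import pytest

from modesign.fixtures import (
    ToyProblemSpec,
    known_front_problem,
    make_two_state_toy,
    ranking_profile_from_model,
)


@pytest.fixture(scope="session")
def toy():
    """Default planted-wild-type two-state toy problem and logit model."""
    return make_two_state_toy(ToyProblemSpec(seed=0))


@pytest.fixture(scope="session")
def toy_profile(toy):
    _, model = toy
    return ranking_profile_from_model(model)


@pytest.fixture(scope="session")
def small_front():
    """Enumerable biobjective problem with its exact Pareto set."""
    return known_front_problem(4, seed=0)


def random_front(rng: np.random.Generator, n: int, d: int, scale: float = 4.0):
    """n mutually non-dominated points in d dimensions inside [0, scale).

    In 2-D the front is constructed directly (x ascending, y descending);
    in higher dimensions small fronts are drawn by rejection.
    """
    from modesign.engine import non_dominated_sort

    if d == 2:
        x = np.sort(rng.uniform(0, scale, n))
        y = np.sort(rng.uniform(0, scale, n))[::-1]
        return np.column_stack([x, y])
    while True:
        P = rng.uniform(0, scale, size=(n, d))
        if len(non_dominated_sort(P).fronts[0]) == n:
            return P
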