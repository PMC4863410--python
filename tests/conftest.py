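import numpy as np
import pytest
import sympy as sp

from crnsteady.examples import (
    four_state_chain_network,
    six_state_network,
    three_state_feedback_network,
)
from crnsteady.model import positive_symbol
from crnsteady.solver import solve_steady_state


def sym(name: str) -> sp.Symbol:
    return positive_symbol(name)


@pytest.fixture(scope="session")
def six_state():
    return six_state_network()


@pytest.fixture(scope="session")
def four_state():
    return four_state_chain_network()


@pytest.fixture(scope="session")
def three_state():
    return three_state_feedback_network()


@pytest.fixture(scope="session")
def six_state_solution(six_state):
    return solve_steady_state(six_state)


@pytest.fixture(scope="session")
def three_state_solution(three_state):
    return solve_steady_state(three_state)


def evaluate_positive(exprs, symbols, rng, n=50, low=0.1, high=10.0):
    """Sample log-uniform positive values for ``symbols`` and evaluate
    ``exprs``; returns array of shape (n, len(exprs))."""
    fn = sp.lambdify([list(symbols)], sp.Matrix(list(exprs)), "numpy")
    out = np.empty((n, len(exprs)))
    lo, hi = np.log10(low), np.log10(high)
    for i in range(n):
        vals = 10.0 ** rng.uniform(lo, hi, size=len(symbols))
        out[i] = np.asarray(fn(vals), dtype=float).ravel()
    return out
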