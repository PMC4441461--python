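import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ahp import diabetes
from ahp.hierarchy import DecisionHierarchy, ObjectiveNode
from ahp.judgments import PairwiseComparisonMatrix


@pytest.fixture(scope="session")
def diabetes_hierarchy():
    return diabetes.build_hierarchy()


@pytest.fixture(scope="session")
def diabetes_locals():
    return diabetes.reference_locals()


@pytest.fixture
def minimal_hierarchy():
    """Smallest legal model: a goal, two leaf objectives, two alternatives."""
    return DecisionHierarchy(
        goal="goal",
        objectives=(ObjectiveNode("speed"), ObjectiveNode("cost")),
        alternatives=("A", "B"),
    )


@pytest.fixture
def flat_hierarchy():
    """One level of three objectives over four alternatives — the compact
    model used for simulation-based checks."""
    return DecisionHierarchy(
        goal="pick a treatment",
        objectives=(
            ObjectiveNode("efficacy"),
            ObjectiveNode("safety"),
            ObjectiveNode("tolerability"),
        ),
        alternatives=("A", "B", "C", "D"),
    )


def random_reciprocal_matrix(rng: np.random.Generator, n: int, spread: float = 1.0):
    """A random positive reciprocal matrix (generally inconsistent)."""
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = float(np.exp(rng.normal(scale=spread)))
            A[i, j] = a
            A[j, i] = 1.0 / a
    return PairwiseComparisonMatrix(
        tuple(f"i{k}" for k in range(n)), A, scale_mode="free"
    )


def consistent_matrix(weights):
    """Perfectly consistent matrix a_ij = w_i / w_j."""
    w = np.asarray(weights, dtype=float)
    A = np.outer(w, 1.0 / w)
    np.fill_diagonal(A, 1.0)
    return PairwiseComparisonMatrix(
        tuple(f"i{k}" for k in range(len(w))), A, scale_mode="free"
    )
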