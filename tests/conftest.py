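import numpy as np
import pytest

from dynsig import ExpressionMatrix, StateMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, two balanced classes."""
    values = np.array([[0.0, 3.0, 6.0, 9.0],
                       [5.0, 5.0, 5.0, 5.0],
                       [1.0, 2.0, 3.0, 4.0]])
    return ExpressionMatrix(values, ["gA", "gB", "gC"],
                            ["s1", "s2", "s3", "s4"],
                            np.array(["c1", "c1", "c2", "c2"], dtype=object))


@pytest.fixture
def separable_states() -> StateMatrix:
    """Two genes, 5+5 samples: class1 all (D, D), class2 all (U, U)."""
    n = 5
    states = np.array([[0] * n + [2] * n, [0] * n + [2] * n], dtype=np.int8)
    labels = np.array(["c1"] * n + ["c2"] * n, dtype=object)
    ids = [f"s{i}" for i in range(2 * n)]
    return StateMatrix(states, ["g1", "g2"], ids, labels)


def random_states(rng, n_genes, n_samples) -> np.ndarray:
    return rng.integers(0, 3, size=(n_genes, n_samples)).astype(np.int8)
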