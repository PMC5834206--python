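import numpy as np
import pytest

from emapnet import InteractionMatrix, call_significant


@pytest.fixture
def tiny_matrix():
    """2x3 matrix with one masked cell (5 scored, 1 masked)."""
    scores = np.array([[1.0, -2.7, 0.3], [2.5, 0.0, -0.1]])
    mask = np.zeros((2, 3), dtype=bool)
    mask[1, 1] = True
    return InteractionMatrix(
        queries=["QA", "QB"],
        tests=["T1", "T2", "T3"],
        condition="untreated",
        scores=scores,
        mask=mask,
    )


@pytest.fixture
def toy_calls():
    """5x8 screen with three significant interactions (two +, one -)."""
    rng = np.random.default_rng(3)
    scores = rng.normal(0, 1, (5, 8))
    scores[0, 0] = 4.0
    scores[1, 1] = -3.0
    scores[2, 0] = 2.5
    matrix = InteractionMatrix(
        queries=[f"q{i}" for i in range(5)],
        tests=[f"t{j}" for j in range(8)],
        condition="toy",
        scores=scores,
        mask=np.zeros((5, 8), dtype=bool),
    )
    return call_significant(matrix, mode="static")
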