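import numpy as np
import pytest

from multimark import ExpressionMatrix, SimulationConfig, simulate


@pytest.fixture
def small_matrix():
    """4 genes x 3 cells, raw counts."""
    values = np.array(
        [
            [0.0, 2.0, 4.0],
            [1.0, 1.0, 1.0],
            [5.0, 0.0, 3.0],
            [2.0, 2.0, 8.0],
        ]
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=["a", "b", "c", "d"],
        cell_ids=["c1", "c2", "c3"],
        scale="raw_counts",
    )


@pytest.fixture(scope="session")
def reference_sim():
    """One draw at the reference conditions (500 cells, 1000 genes, 40 markers)."""
    return simulate(SimulationConfig(seed=7))


def fig1_binary_pattern():
    """Binary pattern realising the two-module/two-population schematic:
    genes g1-g3 on in cells 0-5, g6-g7 on in cells 6-11, g4/g5 sporadic."""
    pattern = {
        "g1": [1] * 6 + [0] * 6,
        "g2": [1] * 6 + [0] * 6,
        "g3": [1] * 6 + [0] * 6,
        "g4": [1, 1] + [0] * 10,
        "g5": [0, 0, 1, 1] + [0] * 8,
        "g6": [0] * 6 + [1] * 6,
        "g7": [0] * 6 + [1] * 6,
    }
    return list(pattern), np.array(list(pattern.values()), dtype=np.int8)


@pytest.fixture
def fig1_matrix():
    """Log-scale expression realising the schematic binary pattern (on = 5)."""
    gene_ids, x = fig1_binary_pattern()
    return ExpressionMatrix(
        values=x * 5.0,
        gene_ids=gene_ids,
        cell_ids=[f"c{j}" for j in range(x.shape[1])],
        scale="log",
    )
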