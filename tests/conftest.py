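import numpy as np
import pandas as pd
import pytest

from gravisig.io import DEGTable, ExpressionMatrix, GeneSet, InteractionTable


@pytest.fixture
def small_deg() -> DEGTable:
    """Three-gene DE table exercising both threshold boundaries."""
    return DEGTable(
        pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "log2fc": [0.3, -0.05, 0.2],
                "p": [0.005, 0.0005, 0.1],
                "adj_p": [0.01, 0.001, 0.2],
            }
        )
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Deterministic 6-gene x 4-sample matrix, two conditions."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 20, size=(6, 4))
    return ExpressionMatrix(
        genes=[f"G{i}" for i in range(1, 7)],
        samples=[f"S{i}" for i in range(1, 5)],
        counts=counts,
        condition=["uG", "uG", "1G", "1G"],
    )


@pytest.fixture
def interactions() -> InteractionTable:
    return InteractionTable(
        pd.DataFrame(
            {
                "compound_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
                "compound_class": ["drug"] * 6,
                "gene": ["A", "B", "B", "C", "D", "E"],
                "score": [900.0, 300.0, 700.0, 150.0, 650.0, 720.0],
            }
        )
    )


@pytest.fixture
def senmayo_like() -> GeneSet:
    return GeneSet("SenMayoLike", frozenset({"IL6", "CXCL8", "IGFBP3"}))
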