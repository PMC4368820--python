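import numpy as np
import pandas as pd
import pytest

from hta.data import CohortDesign, ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 features x 4 samples, deterministic values."""
    rng = np.random.default_rng(12345)
    values = rng.normal(7.0, 1.0, size=(4, 4))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(4)],
            columns=["t1", "t2", "c1", "c2"],
        )
    )


@pytest.fixture
def tiny_design() -> CohortDesign:
    return CohortDesign(test_samples=["t1", "t2"], control_samples=["c1", "c2"])


@pytest.fixture
def medium_null():
    """A noise-only triplicate contrast, large enough for calibration checks."""
    rng = np.random.default_rng(777)
    nf = 5000
    template = rng.normal(7.0, 2.0, size=nf)
    values = template[:, None] + rng.normal(0.0, 0.2, size=(nf, 6))
    matrix = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i:05d}" for i in range(nf)],
            columns=["t1", "t2", "t3", "c1", "c2", "c3"],
        )
    )
    design = CohortDesign(
        test_samples=["t1", "t2", "t3"], control_samples=["c1", "c2", "c3"]
    )
    return matrix, design
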