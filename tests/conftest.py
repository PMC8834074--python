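import numpy as np
import pandas as pd
import pytest

from qdgame.data import ExpressionTable


@pytest.fixture
def small_table():
    """4 genes x 6 samples, two units x two groups plus spares."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(0.5, 5.0, size=(4, 6)),
        index=[f"g{i}" for i in range(1, 5)],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    meta = pd.DataFrame({
        "unit_id": ["u1", "u1", "u2", "u2", "u3", "u3"],
        "group_label": ["type1", "type2"] * 3,
        "stage": ["early"] * 4 + ["late"] * 2,
    }, index=values.columns)
    return ExpressionTable(values, meta)


@pytest.fixture
def power_series():
    """Noise-free y = 2 x^0.5 on a positive grid."""
    from qdgame.data import IndexedSeries

    x = np.array([1.0, 4.0, 9.0, 16.0, 25.0])
    return IndexedSeries(x, 2.0 * x ** 0.5)
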