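import numpy as np
import pandas as pd
import pytest

from coxfilter import ExpressionMatrix


@pytest.fixture
def toy6():
    """n=6 survival data, 3 per subtype, distinct event times, mixed X."""
    return dict(
        x=np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5]),
        i_c2=np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
        time=np.array([3.0, 1.0, 5.0, 2.0, 6.0, 4.0]),
        event=np.array([1, 1, 1, 1, 1, 1]),
    )


@pytest.fixture
def toy8():
    """n=8, 4 per subtype, no censoring, distinct times (fixed fixture)."""
    return dict(
        x=np.array([0.2, 1.4, -0.6, 0.9, -1.1, 0.3, 1.8, -0.4]),
        i_c2=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]),
        time=np.array([4.0, 1.0, 7.0, 3.0, 8.0, 2.0, 6.0, 5.0]),
        event=np.ones(8, dtype=int),
    )


@pytest.fixture
def aligned_cohort():
    """Small aligned log2 expression + clinical pair (20 samples, 5 genes)."""
    rng = np.random.default_rng(42)
    n = 20
    ids = [f"S{i:03d}" for i in range(n)]
    matrix = ExpressionMatrix(
        [f"G{j}" for j in range(5)], ids,
        rng.normal(3, 1, size=(5, n)), "log2p1",
    )
    clinical = pd.DataFrame({
        "sample_id": ids,
        "os_time": rng.exponential(1000, n).round(1),
        "os_event": rng.integers(0, 2, n),
        "subtype": ["c1"] * 10 + ["c2"] * 10,
    })
    if clinical["os_event"].sum() == 0:
        clinical.loc[0, "os_event"] = 1
    return matrix, clinical
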