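import numpy as np
import pandas as pd
import pytest

from gravitome.expression import ExpressionMatrix


def make_matrix(group_values: dict[str, list[list[float]]], probe_ids=None,
                campaign_id="test", scale="linear") -> ExpressionMatrix:
    """Build an ExpressionMatrix from {group: rows-per-probe × samples} lists."""
    n_probes = len(next(iter(group_values.values())))
    if probe_ids is None:
        probe_ids = [f"PS{i:03d}" for i in range(n_probes)]
    columns = {}
    groups = {}
    for g, rows in group_values.items():
        arr = np.asarray(rows, dtype=float)
        for j in range(arr.shape[1]):
            sid = f"{g}.{j + 1}"
            columns[sid] = arr[:, j]
            groups[sid] = g
    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_set_id"))
    return ExpressionMatrix(values, groups, campaign_id=campaign_id, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def two_group_matrix(rng):
    """Null two-group matrix: 50 probe sets, 6 samples per group, sigma 0.1."""
    base = rng.uniform(4, 12, size=50)
    a = 2 ** (base[:, None] + rng.normal(0, 0.1, (50, 6)))
    b = 2 ** (base[:, None] + rng.normal(0, 0.1, (50, 6)))
    return make_matrix({"HW_1g_GC": a.tolist(), "BL_hyp_g": b.tolist()})
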