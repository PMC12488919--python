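import numpy as np
import pandas as pd
import pytest

from sexshift.io import ExpressionMatrix, SampleDesign


def make_dataset(group_values: dict[tuple[str, str], np.ndarray],
                 probe_ids: list[str] | None = None
                 ) -> tuple[ExpressionMatrix, SampleDesign]:
    """Build a matrix+design from {(sex, dose): probes x n array} blocks."""
    columns, rows, blocks = [], [], []
    for (sex, dose), block in group_values.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        blocks.append(block)
        for i in range(block.shape[1]):
            sid = f"{sex}_{dose}_{i + 1}"
            columns.append(sid)
            rows.append({"sample_id": sid, "sex": sex, "dose": dose})
    values = np.concatenate(blocks, axis=1)
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(values.shape[0])]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=columns))
    return matrix, SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """3 probes x 4 samples (2 control F, 2 control M), values on the 0-20 scale."""
    return make_dataset({
        ("F", "control"): rng.uniform(2, 12, (3, 2)),
        ("M", "control"): rng.uniform(2, 12, (3, 2)),
    })
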