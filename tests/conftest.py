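import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from longomix.preprocess import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(abund: np.ndarray, days=(3.0, 5.0, 7.0), reps=1, rt=None) -> FeatureTable:
    """Small hand-built table: one test + one control replicate set per day."""
    n_feat = abund.shape[0]
    sample_rows = []
    for cond in ("test", "control"):
        for rep in range(1, reps + 1):
            for day in days:
                sample_rows.append((f"{cond}_r{rep}_d{day:g}", cond, float(day), rep))
    meta = pd.DataFrame(sample_rows,
                        columns=["sample_id", "condition", "day", "replicate"]
                        ).set_index("sample_id")
    assert abund.shape[1] == len(meta)
    fids = [f"F{i:03d}" for i in range(n_feat)]
    ab = pd.DataFrame(abund, index=fids, columns=meta.index)
    fm = None
    if rt is not None:
        fm = pd.DataFrame({"rt": rt}, index=fids)
    return FeatureTable(ab, meta, fm)


@pytest.fixture
def tiny_table():
    ab = np.array([
        [10.0, 20.0, 30.0, 10.0, 10.0, 10.0],
        [5.0, 5.0, 5.0, 10.0, 10.0, 10.0],
    ]) * 1e4
    return make_table(ab)
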