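import numpy as np
import pytest

import dactynet as dn


@pytest.fixture(scope="session")
def paperlike_data():
    """One paperlike synthetic dataset shared across read-only tests."""
    cfg = dn.paperlike_preset(seed=1)
    return dn.simulate(cfg)


@pytest.fixture(scope="session")
def filtered_paperlike(paperlike_data):
    table, meta, tax, truth = paperlike_data
    filtered, report, flagged = dn.apply_filters(table, tax)
    return filtered, meta, truth, report


@pytest.fixture()
def small_table():
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 1],
            [4, 0, 0, 2],
            [0, 0, 7, 0],
        ]
    )
    return dn.OtuTable(["s1", "s2", "s3", "s4"], ["o1", "o2", "o3", "o4"], counts)
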