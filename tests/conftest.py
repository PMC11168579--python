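import numpy as np
import pandas as pd
import pytest

from cellnerve import build_nerve, make_hex_fixture


@pytest.fixture(scope="session")
def hex_volume():
    return make_hex_fixture()


@pytest.fixture(scope="session")
def hex_nerve(hex_volume):
    return build_nerve(hex_volume)


@pytest.fixture()
def toy_table():
    """Two samples, two tissues, two stages; volumes chosen by hand."""
    rows = []
    for sample, stage in (("s1", "2-I"), ("s2", "2-I"), ("s3", "2-II"), ("s4", "2-II")):
        for cid, (tissue, vol) in enumerate(
            [("L1", 40.0), ("L1", 60.0), ("L2", 100.0), ("L2", 140.0)], start=1
        ):
            rows.append(dict(sample_id=sample, cohort="A", stage=stage,
                             cell_id=cid, tissue_id=tissue, volume=vol))
    df = pd.DataFrame(rows)
    df["stage"] = pd.Categorical(df["stage"], categories=["2-I", "2-II"], ordered=True)
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
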