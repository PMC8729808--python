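import numpy as np
import pandas as pd
import pytest

from methpanel import BetaMatrix, CtTable, SampleRecord
from methpanel.data_model import Group, Location


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_beta_matrix(rng):
    """Random 20-probe x 10-sample matrix with a few missing entries."""
    vals = rng.uniform(0, 1, size=(20, 10))
    vals[2, 3] = np.nan
    vals[7, 0] = np.nan
    probes = [f"cg{i:08d}" for i in range(20)]
    samples = [f"S{i:02d}" for i in range(10)]
    return BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))


@pytest.fixture
def toy_ct_table():
    """Three samples, full gene panel, one NO_AMP, plus calibrator."""
    rows = pd.DataFrame(
        [
            {"sample_id": "S1", "gene": "ACTB", "ct": 27.0},
            {"sample_id": "S1", "gene": "SDC2", "ct": 31.2},
            {"sample_id": "S1", "gene": "TFPI2", "ct": np.nan},
            {"sample_id": "S2", "gene": "ACTB", "ct": 30.0},
            {"sample_id": "S2", "gene": "SDC2", "ct": 39.5},
            {"sample_id": "S2", "gene": "TFPI2", "ct": 33.0},
            {"sample_id": "S3", "gene": "ACTB", "ct": 37.0},
            {"sample_id": "S3", "gene": "SDC2", "ct": 30.0},
            {"sample_id": "S3", "gene": "TFPI2", "ct": 30.0},
        ]
    )
    return CtTable(
        measurements=rows,
        calibrator={"SDC2": 28.0, "TFPI2": 28.5, "ACTB": 25.0},
        negative_control={"ACTB": 30.0},
    )


@pytest.fixture
def toy_records():
    return [
        SampleRecord("S1", Group.CRC, Location.sigmoid_colon, "toy"),
        SampleRecord("S2", Group.CRC, Location.rectum, "toy"),
        SampleRecord("S3", Group.CRC, Location.rectum, "toy"),
        SampleRecord("S4", Group.normal, Location.unknown, "toy"),
        SampleRecord("S5", Group.normal, Location.unknown, "toy"),
    ]
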