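import logging

import numpy as np
import pandas as pd
import pytest

from isletnet.containers import OmicsMatrix, SampleMetadata
from isletnet.synthetic import SimConfig, simulate_study

logging.getLogger("isletnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across test modules."""
    study, table = simulate_study(SimConfig(seed=0))
    return study, table


@pytest.fixture()
def tiny_meta():
    rows = [{"sample_id": f"C{i}", "group": "case"} for i in range(1, 6)] + [
        {"sample_id": f"N{i}", "group": "control"} for i in range(1, 6)
    ]
    return SampleMetadata(pd.DataFrame(rows))


def make_matrix(values, layer="metabolite", feature_meta=None):
    """Helper: OmicsMatrix from a dict/DataFrame of rows."""
    df = pd.DataFrame(values).T if isinstance(values, dict) else values
    return OmicsMatrix(layer, df, feature_meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
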