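import numpy as np
import pandas as pd
import pytest

from lithnet.chrono import identity_curve
from lithnet.typology import MicrolithRecord


@pytest.fixture(scope="session")
def curve():
    """Identity calibration curve covering the study range."""
    return identity_curve(5000.0, 11000.0, sigma=1.0)


def make_record(site="S01", level="L1", traits=("Tra", "As", "RCc", "A", "D")):
    return MicrolithRecord(site, level, tuple(traits))


@pytest.fixture
def toy_records():
    """Three contexts: two sharing types, one all-singleton."""
    t1 = ("Tra", "As", "RCc", "A", "D")
    t2 = ("Seg", "S", "Cv", "AS", "Db")
    t3 = ("Tri", "S", "R", "S", "I")  # occurs once globally
    return [
        make_record("A", "1", t1),
        make_record("A", "1", t2),
        make_record("B", "1", t1),
        make_record("B", "1", t2),
        make_record("C", "1", t3),
    ]


@pytest.fixture
def binary_table():
    """Two contexts over four types: J = 2/4."""
    return pd.DataFrame(
        [[1, 1, 1, 0], [0, 1, 1, 1]],
        index=["A|1", "B|1"],
        columns=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture(scope="session")
def synth_bundle():
    """A fixed synthetic bundle used across pipeline-level tests."""
    from lithnet.synthetic import SynthConfig, generate

    cfg = SynthConfig(
        n_sites=9, n_regions=3, concentration=1.0, count_range=(30, 120),
        levels_per_site=(1, 2), seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
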