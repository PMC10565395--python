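import datetime as dt

import pandas as pd
import pytest

from tidegate.config import StudyConfig
from tidegate.io import Receiver, TagDeployment


@pytest.fixture
def config():
    """Three-month window; local time equals timestamp time (offset 0)."""
    return StudyConfig(
        study_start=dt.date(2020, 1, 1),
        study_end=dt.date(2020, 3, 31),
        local_utc_offset=0.0,
    )


@pytest.fixture
def full_config():
    """The real monitoring window (497-day duration)."""
    return StudyConfig(
        study_start=dt.date(2019, 11, 1),
        study_end=dt.date(2021, 3, 12),
        local_utc_offset=0.0,
    )


@pytest.fixture
def det_factory():
    """Build a detection table from (timestamp, tag, receiver) triples."""

    def make(rows):
        return pd.DataFrame(
            {
                "timestamp": pd.to_datetime([r[0] for r in rows], format="mixed"),
                "tag_id": [str(r[1]) for r in rows],
                "receiver_id": [str(r[2]) for r in rows],
            }
        ).sort_values("timestamp", kind="mergesort").reset_index(drop=True)

    return make


@pytest.fixture
def receivers():
    """Five-receiver gate array 2 km apart on the inlet centreline."""
    return [
        Receiver(
            receiver_id=f"R{i + 1}",
            x=6500.0 + 2000.0 * i,
            y=200.0,
            deploy_date=dt.date(2019, 10, 29),
            recover_date=dt.date(2021, 3, 13),
        )
        for i in range(5)
    ]


@pytest.fixture
def tags():
    return [
        TagDeployment("A", "female", 225.0, dt.date(2019, 10, 29)),
        TagDeployment("B", "male", 190.0, dt.date(2019, 10, 30)),
    ]
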