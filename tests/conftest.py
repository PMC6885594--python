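import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iscsync import RoiTimeseriesDataset, SegmentEntry, SegmentSchedule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """5 subjects x 4 ROIs x 60 timepoints of white noise, TR = 2 s."""
    return RoiTimeseriesDataset(
        data=rng.standard_normal((5, 4, 60)), tr_seconds=2.0
    )


@pytest.fixture
def scheduled_dataset(rng):
    """Dataset with a two-condition block schedule (2 clips x 2 segments)."""
    entries = []
    t = 0
    for condition in ("justified", "unjustified"):
        for clip in (1, 2):
            for segment_type in ("character", "action"):
                entries.append(
                    SegmentEntry(condition, segment_type, clip, t, 10)
                )
                t += 12  # 10 samples + 2-sample interlude
    schedule = SegmentSchedule(entries)
    return RoiTimeseriesDataset(
        data=rng.standard_normal((4, 3, t)),
        tr_seconds=2.0,
        schedule=schedule,
    )
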