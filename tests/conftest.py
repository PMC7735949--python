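import numpy as np
import pytest

from vbikit.behavior_space import GridSpec, PoTGrid
from vbikit.ingest import BehaviorSeries, JointSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20231117)


@pytest.fixture
def small_spec():
    return GridSpec(n_bins=8, wd_range=(0.0, 70.0), logli_range=(0.0, 5.0))


def make_joint(rng, n=500, subject_id="S0"):
    return JointSeries(
        subject_id=subject_id,
        timestamps=np.arange(n) * 5.0,
        wd=rng.uniform(15, 60, n),
        log_li=rng.uniform(0, 4.8, n),
        sample_weight=np.full(n, 5.0),
    )


def random_grid(rng, spec, subject_id="G0"):
    g = rng.random((spec.n_bins, spec.n_bins))
    g /= g.sum()
    return PoTGrid(subject_id=subject_id, grid=g, total_time_s=3600.0, spec=spec)


def make_series(channel, timestamps, values, subject_id="S0"):
    return BehaviorSeries(
        subject_id=subject_id,
        channel=channel,
        timestamps=np.asarray(timestamps, dtype=float),
        values=np.asarray(values, dtype=float),
    )
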