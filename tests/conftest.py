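import numpy as np
import pytest

from hrvnet.model import NetworkConfig
from hrvnet.preprocessing import BeatAnnotatedRR, CohortLabel
from hrvnet.training import TrainConfig


def make_series(intervals, annotations=None, subject_id="s1",
                label=CohortLabel.NSR) -> BeatAnnotatedRR:
    if annotations is None:
        annotations = ["N"] * len(intervals)
    return BeatAnnotatedRR(
        subject_id=subject_id,
        cohort_label=label,
        intervals=tuple(intervals),
        annotations=tuple(annotations),
    )


@pytest.fixture
def tiny_net_cfg() -> NetworkConfig:
    """A depth-2 network small enough for second-scale training tests."""
    return NetworkConfig(depth=2, channels=(3, 4, 5), se_reduction_ratio=2)


@pytest.fixture
def fast_train_cfg() -> TrainConfig:
    return TrainConfig(batch_size=8, epochs=2, seed=7)


@pytest.fixture
def tiny_cohort_segments(tiny_net_cfg):
    """A 6-subject, well-separated cohort segmented at n = 24."""
    from hrvnet.preprocessing import build_dataset
    from hrvnet.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(
        subjects_per_class={CohortLabel.NSR: 3, CohortLabel.CHF: 3},
        beats_per_subject=60,
        seed=11,
    )
    segments, _ = build_dataset(generate_cohort(cfg), n=24,
                                depth=tiny_net_cfg.depth)
    return segments


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
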