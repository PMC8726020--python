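import numpy as np
import pytest

from balancekit import (
    DetectorConfig,
    PipelineConfig,
    build_detector,
    synth_cohort,
)
from balancekit.detector import training_windows


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sit_cohort():
    """Six-subject sit-to-stand cohort shared by the slower tests."""
    return synth_cohort("sit_to_stand", n_normal=4, n_deviating=2, seed=1)


@pytest.fixture(scope="session")
def sit_detector(sit_cohort, cfg):
    """Detector trained on the first five subjects; S006 stays held out."""
    train = [
        (rec, lab) for rec, lab in sit_cohort if rec.subject_id != "S006"
    ]
    x, y, groups = training_windows(train, cfg)
    det = build_detector(DetectorConfig(seed=0), window_len=30)
    det.fit(x, y, groups)
    return det


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
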