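import numpy as np
import pytest

from dermcascade.study import run_detection_study, run_ssl_study


@pytest.fixture(scope="session")
def detection_study(tmp_path_factory):
    """Full five-line desk-scale study: train on a 48-slide mixed cohort,
    evaluate a balanced 60-slide held-out cohort."""
    return run_detection_study(seed=11,
                               work_dir=tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def ssl_study(detection_study):
    """Semi-supervised fine-tuning pass over a weak cohort, warm-started
    from the supervised study's checkpoints."""
    return run_ssl_study(detection_study, seed=31)


@pytest.fixture(scope="session")
def mel_models(detection_study):
    return detection_study.models["mel"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
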