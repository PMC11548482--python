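import numpy as np
import pytest

from glowcurve_qc.ai_filter import train_filter
from glowcurve_qc.datamodel import PipelineConfig
from glowcurve_qc.simulate import generate_labeled_dataset, generate_normal_gc


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def noiseless_normal():
    return generate_normal_gc(0, noise_cv=0.0)


@pytest.fixture(scope="session")
def corpus1608():
    """The default training corpus: 1608 curves, 144 anomalous."""
    return generate_labeled_dataset(1608, seed=1)


@pytest.fixture(scope="session")
def training_report(corpus1608, tmp_path_factory):
    path = tmp_path_factory.mktemp("model") / "filter_model.json"
    cfg = PipelineConfig(training_model_file=str(path))
    return train_filter(corpus1608, seed=1, config=cfg)


@pytest.fixture(scope="session")
def trained_filter(training_report):
    return training_report.model


def flat_curve(value=100.0, overrides=None):
    """A flat 200-channel curve with optional single-channel overrides
    ({1-based channel: value})."""
    y = np.full(200, float(value))
    for ch, v in (overrides or {}).items():
        y[int(ch) - 1] = v
    return y
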