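import numpy as np
import pytest

from dmclibs import (PreprocessConfig, SynthConfig, LineSpec,
                     default_angelica_like_config, generate,
                     preprocess_pipeline, single_line_task_config)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast 2-class dataset: 256-point grid, 3 tablets x 6 shots per class."""
    lines = (
        LineSpec("Na", 589.14, 800.0, 2.0),
        LineSpec("N", 656.26, 700.0, 2.2),
        LineSpec("K", 766.49, 1000.0, 2.6),
        LineSpec("X1", 450.0, 300.0, 2.4),
    )
    mult = np.ones((2, 4))
    mult[0, 1] = 1.4
    mult[1, 1] = 0.7
    return SynthConfig(n_points=256, lines=lines, class_multipliers=mult,
                       baseline_coeffs=(30.0, 60.0, -40.0),
                       noise_sd=5.0, tablets_per_class=3, shots_per_tablet=6,
                       tablet_jitter_sd=0.05,
                       class_names=("Anhui", "Sichuan"), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate(tiny_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-scale dataset: 2 classes x 20 tablets x 50 shots."""
    return generate(default_angelica_like_config(0))


@pytest.fixture(scope="session")
def preprocessed_default(default_dataset):
    return preprocess_pipeline(default_dataset, PreprocessConfig())


@pytest.fixture(scope="session")
def preprocessed_single_line():
    """The saliency benchmark task, dataset-normalised (see methods note)."""
    ds = generate(single_line_task_config(0))
    return preprocess_pipeline(
        ds, PreprocessConfig(normalize=True, normalize_scope="dataset"))
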