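import warnings

import numpy as np
import pytest

from laaoplan.phantom import default_spec, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """One representative phantom: (spec, volume, truth)."""
    spec = default_spec(seed=1)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def clean_report(phantom_case):
    """Full-pipeline report of the representative phantom with the exact oracle."""
    from laaoplan.pipeline import PipelineConfig, run_case
    from laaoplan.predictor import make_oracle

    _, volume, truth = phantom_case
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_case(volume, make_oracle(truth), PipelineConfig(), case_id="phantom_1")
    return report


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
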