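import numpy as np
import pytest

from cemspipe import SyntheticConfig, make_planted_model, run_study, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic study shared across tests."""
    cfg = SyntheticConfig(n_patients=53, seed=1)
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def default_result(default_study):
    """Full pipeline result on the default study."""
    cfg, study = default_study
    model = make_planted_model(study, cfg)
    result = run_study(
        study.samples, study.patients, study.reference_panel,
        study.housekeeping_panel, model,
    )
    return cfg, study, model, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
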