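import numpy as np
import pandas as pd
import pytest

from advicetrial import SimConfig, analysis_records, build_woa_table, simulate_trial


def noise_free_config(**overrides) -> SimConfig:
    """Generator settings under which WOA identifies the true weight exactly:
    deterministic initial estimates at the anchors (all below the advice),
    no response noise, no ties, no dropout, real-valued estimates."""
    base = dict(
        n_participants=80,
        initial_sd=0.0,
        response_sd=0.0,
        participant_weight_sd=0.0,
        tie_probability=0.0,
        dropout_probability=0.0,
        integer_estimates=False,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_trial() -> pd.DataFrame:
    return simulate_trial(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_records(default_trial) -> pd.DataFrame:
    return analysis_records(build_woa_table(default_trial))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
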