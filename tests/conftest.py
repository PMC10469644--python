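import numpy as np
import pytest

import evfingerprint as ef


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient scaled cohort shared across read-only tests."""
    cfg = ef.SimulationConfig(n_patients=60, seed=42).scaled(mean_event_rate_per_ul=150)
    tables, records, truth = ef.simulate_cohort(cfg)
    return cfg, tables, records, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, tables, records, _ = small_cohort
    feats = ef.features_to_frame([ef.build_roi_features(reps) for reps in tables])
    y = (records["grade_group"].to_numpy() >= 3).astype(int)
    return feats, y, records


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
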