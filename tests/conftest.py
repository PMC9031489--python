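import numpy as np
import pandas as pd
import pytest

from neohrv import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220407)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Five short synthetic patients (2 controls, 3 pathological) used by
    the pipeline-level tests."""
    cfg = CohortConfig(n_controls=2, n_pathological=3, record_length_s=720.0, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def blob_table(rng):
    """A per-epoch feature table with a known two-feature class signal and
    one pure-noise feature, for model-stage tests."""
    rows = []
    for p in range(8):
        pid = f"P{p}"
        group = "CP" if p < 3 else "ECP"
        for e in range(30):
            seizure = group != "CP" and e % 5 == 0
            mu = 2.0 if seizure else 0.0
            rows.append({
                "patient_id": pid, "group": group, "epoch_index": e,
                "epoch_start_s": 60.0 * e, "epoch_end_s": 60.0 * (e + 1),
                "label": "seizure" if seizure else "non_seizure",
                "f_signal_a": rng.normal(mu, 1.0),
                "f_signal_b": rng.normal(-mu, 1.0),
                "f_noise": rng.normal(0.0, 1.0),
            })
    return pd.DataFrame(rows)
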