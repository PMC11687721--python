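import numpy as np
import pandas as pd
import pytest

from occucam.detections import DetectionMatrix


@pytest.fixture
def deployments_3x21() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": ["A", "B", "C"],
            "start_date": "2022-12-01",
            "end_date": "2022-12-21",
        }
    )


def make_matrix(values, prefix="occ") -> DetectionMatrix:
    values = np.asarray(values, dtype=float)
    return DetectionMatrix(
        site_ids=[f"s{i + 1}" for i in range(values.shape[0])],
        occasions=[f"{prefix}_{j + 1}" for j in range(values.shape[1])],
        values=values,
    )


@pytest.fixture
def small_study():
    """A tiny synthetic study shared across detection/covariate tests."""
    from occucam import synthetic as syn

    sites = syn.simulate_landscape(20, seed=9)
    beta = np.zeros(8)
    truth = syn.simulate_truth(sites, beta, p=0.4, seed=10)
    records = syn.simulate_records(truth, n_days=21, seed=11)
    deployments = syn.make_deployments(sites["site_id"], n_days=21)
    return sites, truth, records, deployments
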