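import numpy as np
import pandas as pd
import pytest

from dyadpred import SyntheticConfig, generate_study
from dyadpred.study_data import TIMEPOINTS, WAI_TIMEPOINTS, DyadDataset


def make_tiny_dataset() -> DyadDataset:
    """2 therapists, 4 clients, 24 session rows; fully deterministic."""
    therapists = pd.DataFrame({
        "therapist_id": ["T1", "T2"],
        "age": [30.0, 40.0],
        "gender": ["female", "male"],
        "income": [20.0, 30.0],
        "fis_level": ["low", "high"],
        "training": ["trained", "untrained"],
        "orientation": ["focused", "eclectic"],
    })
    clients = pd.DataFrame({
        "client_id": ["C1", "C2", "C3", "C4"],
        "therapist_id": ["T1", "T1", "T2", "T2"],
        "age": [19.0, 20.0, 21.0, 18.0],
        "gender": ["female", "male", "male", "female"],
        "income": [10.0, 12.0, np.nan, 11.0],
        "ssi_total": [250.0, 260.0, 280.0, 240.0],
        "iip_total": [120.0, 140.0, 110.0, 150.0],
        "oq_total_baseline": [70.0, 85.0, 60.0, 90.0],
        "oq_sub_symptom": [40.0, 50.0, 35.0, 55.0],
        "oq_sub_interpersonal": [18.0, 20.0, 15.0, 22.0],
        "oq_sub_social_role": [12.0, 15.0, 10.0, 13.0],
        "prior_treatment": ["no", "yes", "no", "yes"],
    })
    rows = []
    for i, cid in enumerate(clients["client_id"]):
        for j, tp in enumerate(TIMEPOINTS):
            wai = 4.0 + 0.25 * j + 0.1 * i if tp in WAI_TIMEPOINTS else np.nan
            rows.append({"client_id": cid, "timepoint": tp,
                         "wai_client": wai,
                         "wai_therapist": wai + 0.5 if tp in WAI_TIMEPOINTS else np.nan,
                         "oq_total": 80.0 - 3.0 * j + 2.0 * i})
    sessions = pd.DataFrame(rows)
    return DyadDataset(therapists, clients, sessions)


@pytest.fixture
def tiny_dataset() -> DyadDataset:
    return make_tiny_dataset()


@pytest.fixture
def tiny_csvs(tmp_path, tiny_dataset):
    from dyadpred import write_study_tables
    paths = write_study_tables(tiny_dataset, tmp_path)
    return paths


@pytest.fixture(scope="session")
def default_study():
    """Default-design synthetic study (23 therapists x 2 clients)."""
    cfg = SyntheticConfig(seed=5)
    dataset, truth = generate_study(cfg)
    return dataset, truth
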