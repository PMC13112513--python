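import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecsbmr import Dataset, DoseGroup, StudyDatabase, SyntheticConfig, generate_database

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(groups, dataset_id="ds1", technology="DupSeq", chemical="X",
                 covariates=None):
    """Build a Dataset from {dose: [responses]} without ceremony."""
    return Dataset(
        dataset_id=dataset_id,
        technology=technology,
        chemical=chemical,
        covariates=covariates or {},
        groups=[DoseGroup(dose=d, responses=np.asarray(r, float)) for d, r in groups.items()],
    )


@pytest.fixture
def two_study_db():
    """Two DupSeq datasets with control group sizes 3 and 5."""
    ds1 = make_dataset({0.0: [1.0, 1.2, 0.9], 50.0: [2.0, 2.2]}, dataset_id="s1")
    ds2 = make_dataset({0.0: [1.1, 1.0, 1.3, 0.8, 1.2], 25.0: [1.9, 2.1]}, dataset_id="s2")
    return StudyDatabase(datasets=[ds1, ds2])


@pytest.fixture(scope="session")
def small_synth_db():
    """10 noisy datasets from the generative model (no covariates)."""
    cfg = SyntheticConfig(n_datasets=10, var_true=0.05, covariate_design={}, seed=42)
    return generate_database(cfg)


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text(
        "dataset_id,technology,chemical,dose_mg_kg_day,mf_per_1e8bp\n"
        "d1,DupSeq,ENU,0,1.2\n"
        "d1,DupSeq,ENU,0,0.8\n"
        "d1,DupSeq,ENU,50,3.5\n"
    )
    return path
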