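import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from certscore.core_model import CohortFrame, Group, Sex, SubjectRecord
from certscore.synthetic_cohort import generate_study_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_record(id="S-01", **overrides):
    """A complete, physiologically plausible subject for unit tests."""
    base = dict(
        id=id,
        group=Group.NW,
        sex=Sex.F,
        age=30.0,
        smoking=False,
        bmi=22.0,
        wc=78.0,
        sbp=120.0,
        dbp=70.0,
        glucose=87.0,
        insulin=6.65,
        tc=173.0,
        hdl=65.0,
        ldl=106.5,
        tg=63.0,
        crp=0.10,
        cer16=0.4463,
        cer18=0.0663,
        cer241=0.7663,
        cer240=3.7086,
        treated_htn=False,
        diabetes=False,
    )
    base.update(overrides)
    return SubjectRecord(**base)


def random_panel_cohort(rng, n, group=Group.NW.value):
    """Cohort with random lognormal ceramide panels only (tie-free a.s.)."""
    df = pd.DataFrame(
        {
            "id": [f"{group}-{i}" for i in range(n)],
            "group": group,
            "sex": "F",
            "age": 30.0,
            "cer16": np.exp(rng.normal(-0.8, 0.3, n)),
            "cer18": np.exp(rng.normal(-2.5, 0.4, n)),
            "cer241": np.exp(rng.normal(-0.2, 0.3, n)),
            "cer240": np.exp(rng.normal(1.1, 0.3, n)),
        }
    )
    return df


@pytest.fixture(scope="session")
def default_cohort():
    return generate_study_cohort(seed=7)


@pytest.fixture(scope="session")
def default_cohort_df(default_cohort):
    return default_cohort.to_dataframe()


@pytest.fixture()
def tiny_cohort_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    rows = [make_record(id=f"NW-{i:02d}", insulin=6.65 + i) for i in range(3)]
    CohortFrame(subjects=rows).to_dataframe().to_csv(path, index=False)
    return path
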