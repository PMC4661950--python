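import numpy as np
import pandas as pd
import pytest
import yaml

from fosbio import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def tiny_files(tmp_path):
    """A 3-subject, 2-metric CSV with one target column, plus its group map."""
    csv = tmp_path / "cohort.csv"
    csv.write_text(
        "subject,A1,B1,FIM-Total-2w\n"
        "s1,2.0,1.0,60\n"
        "s2,4.0,3.0,80\n"
        "s3,10.0,5.0,100\n",
        encoding="utf-8",
    )
    groups = tmp_path / "groups.yaml"
    groups.write_text(
        yaml.safe_dump(
            {
                "groups": {"A1": "A", "B1": "B"},
                "datasets": {"All": ["A", "B"], "JustA": ["A"]},
                "targets": {"FIM-Total-2w": {"min": 18, "max": 126}},
            }
        ),
        encoding="utf-8",
    )
    return csv, groups


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort, n=120, known 3-term ground truth."""
    cfg = SyntheticCohortConfig(n_subjects=120, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
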