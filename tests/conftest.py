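import numpy as np
import pandas as pd
import pytest

from periopred.chart import CHART_COLUMNS, SITES, validate_dataset
from periopred.synthetic import CohortConfig, generate_cohort


def make_chart_rows(patient_id="P1", fdi=16, ppd=(2, 2, 3, 2, 2, 3),
                    **overrides):
    """Six complete rows (one tooth) with sane defaults; overrides are
    either scalars or per-site sequences."""
    base = {
        "patient_id": patient_id, "fdi": fdi,
        "ppd_t1": 2, "recession_t0": 0,
        "bop_t0": False, "bop_t1": False, "plaque_t0": False,
        "furcation_t0": 0, "mobility": 0,
        "restoration": False, "vitality": True, "percussion": False,
        "cold_sensitivity": True,
        "age": 50, "sex": "male", "bmi": 24.0,
        "antibiotics": False, "family_history": False, "ortho_history": False,
        "diabetes": False, "stress": 5, "smoking_type": "none",
        "cigarettes_per_day": 0,
    }
    base.update(overrides)
    rows = []
    for i, site in enumerate(SITES):
        row = {"site": site, "ppd_t0": ppd[i]}
        for k, v in base.items():
            row[k] = v[i] if isinstance(v, (list, tuple)) else v
        rows.append(row)
    return rows


def chart_frame(rows):
    df = pd.DataFrame(rows)
    for col in CHART_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[list(CHART_COLUMNS)]


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=25, seed=11))


@pytest.fixture(scope="session")
def toy_chart():
    """One patient, one molar, six complete sites."""
    ds, report = validate_dataset(chart_frame(make_chart_rows()))
    assert report.n_rejected == 0
    return ds
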