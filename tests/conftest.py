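import numpy as np
import pandas as pd
import pytest

from fuzzsurv.data_io import Dataset, bin_survival_times
from fuzzsurv.schema import SURVIVAL_CLASS, SURVIVAL_MONTHS, default_schema

#: one valid level per variable, used to pad records in hand-built cohorts
BASE_RECORD = {
    "sex": "male", "age_group": "41-60", "tumor_location": "oral_tongue",
    "t_stage": "T2", "pn_stage": "N0", "tnm_stage": "II",
    "histologic_grade": "well", "ln_metastasis": "negative",
    "lymphovascular_invasion": "negative", "perineural_invasion": "negative",
    "margin": "clear", "extranodal_extension": "negative",
    "primary_treatment": "surgery", "locoregional_recurrence": "none",
    "distant_metastasis": "none",
}


def make_dataset(overrides: list[dict], months: list | None = None) -> Dataset:
    """Build a cohort from per-record predictor overrides of BASE_RECORD."""
    schema = default_schema()
    n = len(overrides)
    rows = [{**BASE_RECORD, **o} for o in overrides]
    df = pd.DataFrame(rows, dtype=object)
    if months is None:
        months = [12] * n
    df[SURVIVAL_MONTHS] = pd.array(months, dtype="Int64")
    cls = [
        None if m is None else int(bin_survival_times(np.array([m]))[0])
        for m in months
    ]
    df[SURVIVAL_CLASS] = pd.array(cls, dtype="Int64")
    return Dataset(df=df, schema=schema)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def labeled_cohort():
    """A deterministic 60-record labeled cohort covering all six classes."""
    months = ([6] * 14 + [18] * 12 + [30] * 10 + [40] * 8 + [55] * 6 + [90] * 10)
    overrides = [{"sex": "male" if i % 2 else "female"} for i in range(60)]
    return make_dataset(overrides, months)
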