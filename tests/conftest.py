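import numpy as np
import pandas as pd
import pytest

from gcsimpute.cohort import simulate_cohort
from gcsimpute.config import TIMEPOINTS, CohortConfig


def toy_patient(sums_by_tp: dict, pupils_by_tp: dict | None = None) -> dict:
    """One patient row whose per-time-point GCS sums equal the given
    values (built as E=sum-11 clipped style: use E4 V5 M(sum-9) when
    possible, else small components)."""
    row: dict = {"patient_id": 0.0, "transfer": 1.0, "stratum": "icu"}
    for tp in TIMEPOINTS:
        s = sums_by_tp.get(tp)
        if s is None:
            e = v = m = np.nan
        else:
            # decompose a sum in [3, 15] into valid components
            m = min(6, s - 2)
            rem = s - m
            v = min(5, rem - 1)
            e = rem - v
        row[f"eye_{tp}"] = float(e)
        row[f"verbal_{tp}"] = float(v)
        row[f"motor_{tp}"] = float(m)
        p = (pupils_by_tp or {}).get(tp, np.nan)
        row[f"pupils_{tp}"] = float(p)
    return row


def toy_cohort(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows).reset_index(drop=True)


@pytest.fixture(scope="session")
def default_cohort():
    """A 2000-patient synthetic cohort under default study conditions."""
    cohort, truth = simulate_cohort(CohortConfig(n_patients=2000, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def large_cohort():
    """10k patients for Monte-Carlo property checks."""
    cohort, truth = simulate_cohort(CohortConfig(n_patients=10_000, seed=7))
    return cohort, truth
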