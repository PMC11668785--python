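import numpy as np
import pandas as pd
import pytest

from crlandmark import (SimulationConfig, simulate_cohort, prepare_cohort,
                        impute_baseline, locf_fill)
from crlandmark.cohort import PatientTimeline


@pytest.fixture(scope="session")
def sim_tables():
    """A medium synthetic cohort shared across test modules."""
    cfg = SimulationConfig(n_patients=300, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def timelines(sim_tables):
    meas, demo, out, _ = sim_tables
    tls, _ = prepare_cohort(meas, demo, out)
    return tls


@pytest.fixture(scope="session")
def filled_timelines(timelines):
    tls = impute_baseline(timelines, seed=0)
    return [locf_fill(tl) for tl in tls]


def make_timeline(patient_id=0, sex="F", age=60.0, gn=np.nan,
                  series=None, cause=0, event_time=np.nan,
                  time0="2010-01-15", last_test=None) -> PatientTimeline:
    """Hand-built timeline for unit tests; series maps analyte -> {month: value}."""
    ser = {a: pd.Series(v, dtype=float).sort_index()
           for a, v in (series or {}).items()}
    t0 = pd.Timestamp(time0)
    last = pd.Timestamp(last_test) if last_test else t0 + pd.Timedelta(days=365)
    return PatientTimeline(patient_id=patient_id, sex=sex, age_at_time0=age,
                           gn_vasculitis=gn, time0_date=t0, series=ser,
                           cause=cause, event_time=event_time,
                           last_test_date=last)
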