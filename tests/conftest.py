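"""Shared fixtures: parameter table, tiny hand-built timelines, small cohorts."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from earlywarn.ehr import AdmissionTimeline
from earlywarn.parameters import load_parameter_table, parameter_names

T0 = pd.Timestamp("2020-03-01 00:00")


def make_timeline(events, admit=None, discharge=None, admission_id="A1", patient_id="P1"):
    """Build a timeline from (hours_after_admit, parameter, value) triples."""
    admit = T0 if admit is None else admit
    rows = [
        {"timestamp": admit + pd.Timedelta(hours=h), "parameter": p, "value": float(v)}
        for h, p, v in events
    ]
    last = max((r["timestamp"] for r in rows), default=admit)
    discharge = discharge if discharge is not None else max(last, admit + pd.Timedelta(hours=1))
    return AdmissionTimeline(
        admission_id=admission_id,
        patient_id=patient_id,
        admit_time=admit,
        discharge_time=discharge,
        events=pd.DataFrame(rows, columns=["timestamp", "parameter", "value"]),
    )


@pytest.fixture(scope="session")
def table():
    return load_parameter_table()


@pytest.fixture(scope="session")
def param_names(table):
    return parameter_names(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
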