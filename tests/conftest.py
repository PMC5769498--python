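import numpy as np
import pytest

from emtdx.cohort import CohortTable, SubjectRecord


def make_record(i, stage="local", n_stage="not_applicable", marker=1.0, **kw):
    defaults = dict(
        subject_id=f"s{i}",
        stage=stage,
        n_stage=n_stage,
        marker_score=marker,
        followup_time=kw.pop("followup_time", 3.0),
        death=kw.pop("death", 0),
    )
    defaults.update(kw)
    return SubjectRecord(**defaults)


@pytest.fixture
def printed_stage_cohort():
    """188 subjects with the published stage distribution: 99 local, 66
    regional, 23 distant (3 N0, 11 N1/N2, 9 unknown N-stage)."""
    records = []
    i = 0
    for _ in range(99):
        records.append(make_record(i, stage="local"))
        i += 1
    for _ in range(66):
        records.append(make_record(i, stage="regional"))
        i += 1
    for n_stage, count in (("N0", 3), ("N1orN2", 11), ("unknown", 9)):
        for _ in range(count):
            records.append(make_record(i, stage="distant", n_stage=n_stage))
            i += 1
    return CohortTable(records=records)


@pytest.fixture
def toy_cox_data():
    """Six subjects: times 1..6, events 1,1,1,0,0,0, binary x 1,1,0,1,0,0."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 1, 1, 0, 0, 0])
    x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
    return x, times, events


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
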