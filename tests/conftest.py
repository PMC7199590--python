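import numpy as np
import pytest

from rdwprog import CohortTable, PatientRecord, RDWSeries
from rdwprog.synthetic_cohort import GeneratorConfig, generate_cohort


def make_record(pid="p1", **kw):
    defaults = dict(
        patient_id=pid,
        age=60.0,
        sex="female",
        comorbidity_category="1",
        sofa=10,
        pf_ratio=150.0,
        rdw_baseline=15.0,
        icu_death=False,
        hosp_death=False,
        death_90d=False,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration synthetic cohort at the published sample size."""
    cohort, series = generate_cohort(GeneratorConfig(n=318, seed=1))
    return cohort, series


@pytest.fixture
def small_cohort():
    """Ten hand-built patients with a mix of covariates and outcomes."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(10):
        dead = i < 4
        records.append(
            make_record(
                pid=f"s{i}",
                age=float(rng.uniform(20, 90)),
                sex="male" if i in (0, 2, 3, 5, 8) else "female",
                comorbidity_category=("0", "1", "2", "3plus")[i % 4],
                sofa=int(rng.integers(0, 25)),
                pf_ratio=float(rng.uniform(50, 350)),
                rdw_baseline=float(rng.uniform(12, 20)),
                icu_death=dead,
                hosp_death=dead,
                death_90d=dead,
            )
        )
    return CohortTable(records=tuple(records))


def series_from(pid, times, values):
    return RDWSeries(patient_id=pid, times=tuple(times), values=tuple(values))
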