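import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from latedose import RuleConfig, ScenarioSpec, TrialConfig, builtin_scenario, load_default_weights
from latedose.dataset import PatientRecord, ToxDataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DOSES = (1.5, 2.5, 3.5, 4.5, 6.0, 7.0)


@pytest.fixture(scope="session")
def weights():
    return load_default_weights()


@pytest.fixture(scope="session")
def scenario_d():
    return builtin_scenario("D")


@pytest.fixture
def config_s1():
    return TrialConfig(rules=RuleConfig(setting=1))


@pytest.fixture
def config_s2():
    return TrialConfig(rules=RuleConfig(setting=2))


def make_record(patient, dose, u, dlt_cycle=None, dose_values=DOSES, grades=None):
    """Build a consistent PatientRecord for fixtures."""
    if grades is None:
        grades = [1] * u
        if dlt_cycle is not None:
            grades[dlt_cycle - 1] = 3
    cats = tuple(3 if g >= 3 else (2 if g == 2 else 1) for g in grades)
    return PatientRecord(
        patient=patient,
        dose=dose,
        dose_value=dose_values[dose],
        cycles_observed=u,
        dlt_cycle=dlt_cycle,
        categories=cats,
        max_grades=tuple(grades),
        nttp=tuple(0.1 * g for g in grades),
    )


def make_dataset(records, n_cycles=3, dose_values=DOSES):
    return ToxDataset(tuple(records), n_cycles, dose_values)


@pytest.fixture
def make_rec():
    return make_record


@pytest.fixture
def make_ds():
    return make_dataset
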