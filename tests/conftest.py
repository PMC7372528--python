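import dataclasses

import pytest

from trialcea.costing import UnitCostTable
from trialcea.synthetic_data import SimulationConfig, generate_trial
from trialcea.trial_data import AssessmentWave, PatientRecord, TrialDataset
from trialcea.utility_qaly import MappingCoefficients


def make_patient(
    pid="P1",
    arm="SIW",
    region="Balearic",
    gp=None,
    contacts=3.0,
    products=("Lorazepam", "Lorazepam", "Lorazepam"),
    hads=((5, 5), (4, 4), (3, 3)),
    times=(0.0, 0.5, 1.0),
    initial=None,
):
    """Hand-build one valid patient record for unit tests."""
    waves = [
        AssessmentWave(
            time_years=t,
            hads_a=None if h is None else h[0],
            hads_d=None if h is None else h[1],
            benzo_product=p,
        )
        for t, h, p in zip(times, hads, products)
    ]
    return PatientRecord(
        patient_id=pid,
        gp_id=gp or f"{arm}-G1",
        region=region,
        arm=arm,
        assessments=waves,
        n_contact_visits=contacts,
        had_initial_visit=(arm != "TAU") if initial is None else initial,
    )


@pytest.fixture(scope="session")
def default_costs():
    return UnitCostTable.defaults()


@pytest.fixture(scope="session")
def coeffs():
    return MappingCoefficients.illustrative_default()


@pytest.fixture
def small_dataset():
    patients = [
        make_patient("P1", arm="SIW", region="Balearic"),
        make_patient("P2", arm="SIF", region="Catalunya", contacts=6.0,
                     products=("Alprazolam", "Alprazolam", "None")),
        make_patient("P3", arm="TAU", region="Valencia", contacts=2.0,
                     products=("Diazepam", "Diazepam", "Diazepam")),
    ]
    return TrialDataset.from_patients(patients)


@pytest.fixture(scope="session")
def small_sim_config():
    return dataclasses.replace(
        SimulationConfig(),
        n_patients_per_arm={"SIW": 40, "SIF": 40, "TAU": 40},
        n_gps_per_arm=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One default-size synthetic trial, shared across tests."""
    return generate_trial(SimulationConfig(), seed=123)
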