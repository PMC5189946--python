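"""Shared fixtures: small simulated cohorts and fitted models.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive simulate -> preprocess -> fit path to one execution.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wormescape as we

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def control_spec():
    return we.paper_preset("control")


@pytest.fixture(scope="session")
def control_template(control_spec):
    return we.canonical_template(control_spec)


@pytest.fixture(scope="session")
def control_sim(control_spec):
    """Simulated control cohort (n = 300) with its preprocessed profiles."""
    cohort, truth = we.simulate_cohort(control_spec, 300, seed=101)
    V = we.VelocityPreprocessor().transform(cohort.velocity_matrix)
    return cohort, truth, V, cohort.currents_mA


@pytest.fixture(scope="session")
def ibuprofen_sim():
    cohort, truth = we.simulate_cohort(we.paper_preset("ibuprofen"), 300, seed=102)
    V = we.VelocityPreprocessor().transform(cohort.velocity_matrix)
    return cohort, truth, V, cohort.currents_mA


@pytest.fixture(scope="session")
def control_model(control_sim):
    """Control escape model fitted on the simulated control cohort."""
    _, _, V, I = control_sim
    return we.EscapeResponseModel(n_restarts=3, random_state=0).fit(V, I)
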