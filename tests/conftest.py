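import numpy as np
import pytest

import msmsim as ms


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized observational cohort under the default generator."""
    return ms.simulate_observational(20_000, seed=101)


@pytest.fixture(scope="session")
def default_weights(default_cohort):
    observed = default_cohort.observed()
    fits = ms.fit_treatment_models(observed)
    return ms.compute_stabilized_weights(observed, fits)


@pytest.fixture()
def two_person_panel():
    """Hand-built 2-person panel: one event at 2.3, one administratively censored."""
    return ms.CohortPanel(
        ids=np.array([1, 2]),
        A=np.array([[1, 0, 1, 0, 0], [0, 0, 0, 0, 0]], dtype=np.int8),
        L=np.array(
            [[0.5, -0.25, 1.0, np.nan, np.nan],
             [0.1, 0.2, 0.3, 0.4, 0.5]]
        ),
        atrisk=np.array(
            [[True, True, True, False, False],
             [True, True, True, True, True]]
        ),
        U=np.array([0.05, -0.1]),
        T=np.array([2.3, np.nan]),
        event=np.array([True, False]),
        C=np.array([5.0, 5.0]),
    )


@pytest.fixture()
def unconfounded_specs():
    """Generator with no L/U effect on the hazard and no L effect on treatment."""
    hazard = ms.ConditionalHazardSpec(baseline=0.7, treatment=(-0.2,),
                                      confounder=(0.0,), frailty=0.0)
    treatment = ms.TreatmentAssignmentSpec(gammaL=0.0)
    return hazard, treatment
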