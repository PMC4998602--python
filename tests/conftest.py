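import numpy as np
import pytest

from periprog.grid import build_grid
from periprog.normative import fit_normative
from periprog.synthetic_data import (
    SimulationConfig,
    simulate_normative_cohort,
    simulate_patient_cohort,
)


@pytest.fixture(scope="session")
def grid_od():
    return build_grid("OD")


@pytest.fixture(scope="session")
def normative_cohort():
    """Default-size normative cohort (207 subjects x 3 modalities)."""
    return simulate_normative_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def normative_model(normative_cohort):
    return fit_normative(normative_cohort)


@pytest.fixture(scope="session")
def small_patient_cohort():
    """A small paired longitudinal cohort plus ground-truth labels."""
    config = SimulationConfig(seed=2, n_patients=20, n_eyes=26)
    return simulate_patient_cohort(config)


def make_field(sens, modality="SAP", age=60.0, **kwargs):
    """Convenience constructor for a well-formed VisualField."""
    from datetime import date

    from periprog.fields_io import VisualField

    defaults = dict(
        subject_id="T000",
        eye="OD",
        modality=modality,
        test_date=date(2015, 6, 1),
        age=age,
        sens_db=np.asarray(sens, dtype=float),
        fixation_loss=0.05,
        false_neg=0.05,
        false_pos=0.05,
    )
    defaults.update(kwargs)
    return VisualField(**defaults)
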