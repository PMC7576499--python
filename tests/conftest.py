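import pytest

from nipflow.kinetics import CellGeometry, ShockConditions
from nipflow.synthetic_data import (
    SyntheticStructureSpec,
    default_simulation_params,
    make_channel_structure,
)

# Native aquaglyceroporin parameters used as generating ground truth
# throughout the suite (strain "NIP1;1"): high glycerol and moderate water
# permeability with their activation energies.
NIP11 = {
    "pf_true": 6.78e-4,  # cm/s
    "pgly_true": 24.5e-8,  # cm/s
    "ea_water": 9.80,  # kcal/mol
    "ea_glycerol": 6.93,  # kcal/mol
}


@pytest.fixture
def geometry():
    return CellGeometry()


@pytest.fixture
def water_conditions():
    return ShockConditions(shock_solute="sorbitol")


@pytest.fixture
def glycerol_conditions():
    return ShockConditions(shock_solute="glycerol")


@pytest.fixture
def water_params():
    return default_simulation_params(**NIP11, shock_solute="sorbitol", seed=1)


@pytest.fixture
def glycerol_params():
    return default_simulation_params(**NIP11, shock_solute="glycerol", seed=1)


@pytest.fixture(scope="session")
def cylinder_structure():
    return make_channel_structure(SyntheticStructureSpec())


@pytest.fixture(scope="session")
def hourglass_spec():
    return SyntheticStructureSpec(constriction_radius=1.4, constriction_z=20.0)


@pytest.fixture(scope="session")
def hourglass_structure(hourglass_spec):
    return make_channel_structure(hourglass_spec)
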