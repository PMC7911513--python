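import numpy as np
import pytest
from hypothesis import settings

from platekd import (
    EvaporationParams,
    FormulationTruth,
    InstrumentConfig,
    PlateLayout,
)
from platekd.plate_model import WellAddress, WellAssignment

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture
def noiseless_instrument() -> InstrumentConfig:
    return InstrumentConfig(noise_sigma0=0.0)


@pytest.fixture
def lysozyme_truth() -> FormulationTruth:
    return FormulationTruth.from_radius("lys", 1.9, 91.8)


def make_block_layout(
    concentrations=(2.0, 5.0, 10.0, 14.0),
    replicates: int = 5,
    row0: int = 3,
    col0: int = 8,
    formulation_id: str = "lys",
    plate_id: str = "test-block",
) -> PlateLayout:
    """A small center block: concentrations across columns, replicates down."""
    layout = PlateLayout(plate_id=plate_id)
    for j, conc in enumerate(concentrations):
        for r in range(replicates):
            layout.add(
                WellAssignment(
                    address=WellAddress(row0 + r, col0 + j),
                    formulation_id=formulation_id,
                    concentration_mg_ml=float(conc),
                )
            )
    return layout


@pytest.fixture
def block_layout() -> PlateLayout:
    return make_block_layout()
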