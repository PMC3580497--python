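import numpy as np
import pytest

from algscreen.plate_io import (
    ROLE_COMPOUND,
    ROLE_CONTROL,
    PlateLayout,
    WellRole,
    WellSeries,
    plate_addresses,
)


def make_series(times, od, plate_id="P1", well="A1"):
    return WellSeries(plate_id=plate_id, well=well, times=np.asarray(times, float), od=np.asarray(od, float))


@pytest.fixture
def full_96_layout():
    """96-well layout: 4 controls in column 12 of rows A-D, compounds elsewhere."""
    controls = {"A12", "B12", "C12", "D12"}
    wells = {}
    i = 0
    for addr in plate_addresses(96):
        if addr in controls:
            wells[addr] = WellRole(ROLE_CONTROL)
        else:
            i += 1
            wells[addr] = WellRole(ROLE_COMPOUND, compound_id=f"C{i:03d}", dose_uM=25.0)
    return PlateLayout(plate_id="P1", wells=wells, geometry=96)


@pytest.fixture
def rng():
    return np.random.default_rng(20121118)
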