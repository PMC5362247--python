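import pytest

from screensift import SimConfig, simulate_screen
from screensift.io import (
    MeasurementSet,
    PlateLayout,
    Pool,
    ScreenBundle,
    SiRNALibrary,
    Well,
)

import pandas as pd


def make_tiny_bundle(signals=None):
    """One plate, one replicate: 4 sample wells + 1 scrambled control."""
    wells = {
        "A1": Well("sample", "POOL1"),
        "A2": Well("sample", "POOL2"),
        "A3": Well("sample", "POOL3"),
        "A4": Well("sample", "POOL4"),
        "B1": Well("scrambled_control", "SCRAMBLED"),
    }
    layout = PlateLayout(plate_id="P1", replicate_id="R1", wells=wells)
    signals = signals or {"A1": 10.0, "A2": 20.0, "A3": 30.0, "A4": 40.0, "B1": 25.0}
    meas = MeasurementSet(
        pd.DataFrame(
            [("P1", "R1", w, s) for w, s in signals.items()],
            columns=["plate_id", "replicate_id", "well", "signal"],
        )
    )
    library = SiRNALibrary(
        {
            f"POOL{i}": Pool(gene=f"GENE{i}", sirna_ids=(f"G{i}s1", f"G{i}s2"))
            for i in range(1, 5)
        }
    )
    return ScreenBundle(layouts={("P1", "R1"): layout}, measurements=meas, library=library)


@pytest.fixture
def tiny_bundle():
    return make_tiny_bundle()


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic screen (1,000 genes, seed 17); session-scoped
    because several suites reuse it."""
    return simulate_screen(SimConfig(seed=17))
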