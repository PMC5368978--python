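import numpy as np
import pytest

import redoxflim as rf


@pytest.fixture(scope="session")
def acq() -> rf.AcquisitionSpec:
    """Default acquisition: 80 MHz (12.5 ns window), 256 bins."""
    return rf.AcquisitionSpec()


@pytest.fixture(scope="session")
def probes() -> dict:
    return rf.load_probe_table()


@pytest.fixture(scope="session")
def small_scene():
    """A small rendered control scene shared by I/O and quantification tests."""
    scene, truth = rf.make_scene("control", n_cells=3, shape=(128, 128),
                                 diameter_range=(30.0, 36.0), seed=5)
    stack = rf.render_flim(scene, truth, rf.AcquisitionSpec(), seed=6)
    return scene, truth, stack
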