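import numpy as np
import pytest

from aortamihc import default_cohort_config
from aortamihc.gating import gate_cells
from aortamihc.panels import PANELS
from aortamihc.simulate import _make_geometry, generate_slide


@pytest.fixture(scope="session")
def config():
    return default_cohort_config(master_seed=12345)


@pytest.fixture(scope="session")
def dilated_slide(config):
    """One default dilated slide with guaranteed planted TLS (~20k cells)."""
    rng = np.random.default_rng(7)
    geometry = _make_geometry(config, rng)
    group = config.group("dilated")
    # retry the stochastic TLS coin until the slide carries structures
    for attempt in range(20):
        cells, truth = generate_slide(
            group, geometry, rng, config.intensity_model, config.analysis, "dilated_01"
        )
        if truth.tls:
            return cells, geometry, truth
    raise RuntimeError("no TLS planted in 20 attempts")  # pragma: no cover


@pytest.fixture(scope="session")
def gated_dilated_slide(config, dilated_slide):
    cells, geometry, truth = dilated_slide
    gated = gate_cells(
        cells, PANELS, config.intensity_model, config.analysis,
        markers_masked=config.group("dilated").markers_masked,
    )
    return gated, geometry, truth
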