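import numpy as np
import pytest

from voltsync.preprocess import process_cell, qc_cells
from voltsync.simulate import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One standard synthetic session (14 cells, 180 s) shared by many tests."""
    return generate_session(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def processed_cells(default_session):
    """Per-cell preprocessing results for the standard session, QC applied."""
    bundle, _ = default_session
    acts = [process_cell(c.cell_id, c.raw_f, c.sampling_rate_hz, bundle.duration_s)
            for c in bundle.cells]
    centroids = {c.cell_id: np.asarray(c.centroid_xy) for c in bundle.cells}
    included, analyzable = qc_cells(acts, centroids, bundle.duration_s)
    return acts, included, analyzable


@pytest.fixture(scope="session")
def small_session():
    """A reduced session (10 cells, 120 s) for pipeline-level tests."""
    return generate_session(GeneratorConfig(seed=11, n_cells=10, duration_s=120.0))


def pytest_configure(config):
    try:
        from hypothesis import settings
        settings.register_profile("ci", derandomize=True, max_examples=25,
                                  deadline=None)
        settings.load_profile("ci")
    except ImportError:
        pass
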