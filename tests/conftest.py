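import numpy as np
import pytest

from renalquant import StudyConfig, TissueParams, make_kidney_labelmap
from renalquant.pipeline import run_pipeline

SMALL_SHAPE = (12, 64, 64)
SMALL_SPACING = (4.0, 1.5, 1.5)


@pytest.fixture(scope="session")
def labelmap():
    return make_kidney_labelmap(SMALL_SHAPE, SMALL_SPACING, seed=7)


@pytest.fixture(scope="session")
def tissue():
    return TissueParams()


@pytest.fixture(scope="session")
def cohort_bundle():
    """The default 20-subject two-observer cohort run, shared across tests."""
    return run_pipeline(StudyConfig(seed=20260925))


def circle_vertices(radius, n=64, center=(0.0, 0.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])
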