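import warnings

import numpy as np
import pytest

from epmneg import MazeGeometry, NEGSeries

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def geometry() -> MazeGeometry:
    return MazeGeometry()


@pytest.fixture(scope="session")
def small_geometry() -> MazeGeometry:
    """A 10-segment-per-arm maze for cheap exhaustive checks."""
    return MazeGeometry(arm_length=10.0, arm_width=4.0, centre_size=4.0)


def subsample(series: NEGSeries, step: float) -> NEGSeries:
    keep = np.isclose(series.times % step, 0.0)
    return NEGSeries(series.subject_id, series.scope, series.times[keep], series.neg[keep])
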