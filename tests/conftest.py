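import numpy as np
import pytest

from grousevis.spectra import default_grid


@pytest.fixture(scope="session")
def fine_grid() -> np.ndarray:
    """The 0.1 nm evaluation grid used for peak/cutoff location."""
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid() -> np.ndarray:
    """A 1 nm measurement-like grid (300-700 nm)."""
    return np.arange(300.0, 701.0, 1.0)
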