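import numpy as np
import pytest

from poolkin import (
    FrequencyMatrix,
    GroupSpec,
    SimConfig,
    generate_reference_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fm():
    """3 landraces x 4 loci, complete."""
    return FrequencyMatrix(
        ["L1", "L2", "L3"],
        ["s1", "s2", "s3", "s4"],
        [[0.5, 0.0, 1.0, 0.25],
         [0.5, 0.1, 0.9, 0.75],
         [0.0, 0.0, 1.0, 0.50]],
    )


@pytest.fixture(scope="session")
def two_group_panel():
    """Two diverged groups (realized pairwise Gst near 0.2) with a map."""
    cfg = SimConfig(
        n_loci=600,
        groups=[GroupSpec("A", 15, 1 / 3, 0.02),
                GroupSpec("B", 15, 1 / 3, 0.02)],
        bulk_size=15,
        seed=2,
    )
    fm, pp, panel = generate_reference_panel(cfg)
    return fm, pp, panel
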