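import numpy as np
import pytest

from serumftir import SpectrumSet, SyntheticTruth, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Strong-effect synthetic cohort (n=24, 12/12) under the default truth."""
    sset, sidecar = generate_cohort(SyntheticTruth(seed=11))
    return sset, sidecar


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with all class effects removed (pure technical variation)."""
    sset, sidecar = generate_cohort(SyntheticTruth(seed=11, effect_scale=0.0))
    return sset, sidecar


@pytest.fixture
def tiny_set():
    """4-sample, 5-point toy set with both classes."""
    grid = np.array([1000.0, 1002.0, 1004.0, 1006.0, 1008.0])
    m = np.array(
        [
            [1.0, 2.0, 3.0, 2.0, 1.0],
            [1.1, 2.1, 3.1, 2.1, 1.1],
            [2.0, 1.0, 2.0, 3.0, 2.0],
            [2.1, 1.1, 2.1, 3.1, 2.1],
        ]
    )
    return SpectrumSet(grid, m, ["a", "b", "c", "d"], [0, 0, 1, 1])
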