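import numpy as np
import pytest

import chipdiag as cd


@pytest.fixture
def genome():
    """Two small chromosomes; enough structure for window/bin edge cases."""
    return cd.GenomeLayout([("chrI", 1000), ("chrII", 450)])


@pytest.fixture
def toy_counts():
    """The fixed-threshold estimator's hand fixture."""
    return cd.WindowCounts.from_arrays([0, 1, 0, 3], [1, 0, 1, 4])


def stranded_background_counts(n_windows=20000, mu=8.0, r=0.7, seed=0):
    """Background-only stranded counts with known r (even strand split)."""
    rng = np.random.default_rng(seed)
    cp = rng.poisson(r * mu / 2, n_windows)
    cm = rng.poisson(r * mu / 2, n_windows)
    ip = rng.poisson(mu / 2, n_windows)
    im = rng.poisson(mu / 2, n_windows)
    return cd.WindowCounts.from_arrays(
        cp + cm, ip + im, window_size=1000,
        chip_plus=cp, chip_minus=cm, input_plus=ip, input_minus=im)
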