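import numpy as np
import pytest

from cobbgeo.geometry import SearchConfig, VertebraAngles
from cobbgeo.synthetic import (
    GaussianBump,
    SyntheticSpineSpec,
    generate_spine,
    spec_for_target_cobb,
)


@pytest.fixture
def default_cfg():
    return SearchConfig()


@pytest.fixture
def straight_spine():
    """Noiseless 17-vertebra spine with no lateral deviation."""
    return generate_spine(SyntheticSpineSpec(seed=7))


@pytest.fixture
def single_bump_spine():
    """Noiseless spine with a single 25-degree primary curve."""
    spec = spec_for_target_cobb(25.0, np.random.default_rng(11))
    return generate_spine(spec), spec


def angles_from_tilts(tilts):
    """VertebraAngles list with alpha = beta = theta = tilt (degrees)."""
    return [VertebraAngles(alpha=t, beta=t, theta=t, index=i)
            for i, t in enumerate(tilts)]


def brute_force_end_vertebrae(tilt_alphas, tilt_betas, s, e, min_span, min_angle):
    """Independent exhaustive oracle for the end-vertebra search.

    Plain double loop over all admissible pairs with the acute-angle
    wrap written out directly; first (lexicographically smallest) argmax
    kept; None below the reporting threshold.
    """
    best = None
    for i in range(s, e + 1):
        for j in range(i + min_span, e + 1):
            d = abs(tilt_alphas[i] - tilt_betas[j]) % 180.0
            c = 180.0 - d if d > 90.0 else d
            if best is None or c > best[0]:
                best = (c, i, j)
    if best is None or best[0] < min_angle:
        return None
    return best[1], best[2], best[0]
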