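import numpy as np
import pytest

from spondylograde import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def untilted_phantom():
    """Mid-size phantom with one grade-II slip, no tilt (exact geometry)."""
    spec = PhantomSpec(per_level_slip_ratio=(0.0, 0.0, 0.0, 0.30, 0.0),
                       global_tilt_deg=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_batch():
    """Twenty small phantoms with assorted slips, for training smoke tests."""
    rng = np.random.default_rng(7)
    phantoms = []
    for i in range(20):
        ratios = [0.0] * 5
        if i % 2:
            ratios[int(rng.integers(0, 5))] = float(rng.uniform(0.10, 0.60))
        spec = PhantomSpec.scaled(48, 48, per_level_slip_ratio=tuple(ratios),
                                  seed=int(rng.integers(2**31)))
        phantoms.append(generate_phantom(spec))
    return phantoms
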