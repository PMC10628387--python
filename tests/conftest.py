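import copy

import numpy as np
import pytest

from pcali.fixtures import FamilySpec, evolve_family, make_scaffold


def random_rigid(rng):
    """A random rotation (det +1) and translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.normal(0, 20, 3)
    return R, t


@pytest.fixture(scope="session")
def mixed_scaffold():
    return make_scaffold(60, "mixed")


@pytest.fixture(scope="session")
def rigid_pair(mixed_scaffold):
    """A scaffold and a rigidly transformed copy of it."""
    rng = np.random.default_rng(7)
    R, t = random_rigid(rng)
    other = mixed_scaffold.transformed(R, t)
    other = copy.deepcopy(other)
    other.id = "copy"
    return mixed_scaffold, other


@pytest.fixture(scope="session")
def small_family():
    return evolve_family(FamilySpec(seed=11))


@pytest.fixture(scope="session")
def rigid_family():
    """Six exact rigid copies (zero substitution/indel/noise rates)."""
    spec = FamilySpec(n=4, L=40, subst_rate=0.0, indel_rate=0.0,
                      noise_sigma=0.0, seed=3)
    return evolve_family(spec)
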