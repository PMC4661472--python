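import numpy as np
import pytest

from tmbundle.core import (BundleConfiguration, HelixSegment, MembraneFrame,
                           build_ideal_helix)
from tmbundle.energy import MembraneRestraintParams, default_pair_table
from tmbundle.io import tap1_crosslinks, tap1_segments


def single_site_helix(helix_id, aa, position, chain_id="A", residue=1):
    """One-residue 'helix' whose CA sits exactly at ``position``."""
    seg = HelixSegment(helix_id=helix_id, chain_id=chain_id,
                       start_res=residue, end_res=residue, sequence=aa)
    h = build_ideal_helix(seg)
    return h.with_pose(np.eye(3), np.asarray(position, dtype=float))


def toy_config(*helices):
    return BundleConfiguration(helices=tuple(helices), frame=MembraneFrame())


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-20, 20, 3)


@pytest.fixture(scope="session")
def segments():
    return tap1_segments()


@pytest.fixture(scope="session")
def observations(segments):
    return tap1_crosslinks(segments)


@pytest.fixture(scope="session")
def table():
    return default_pair_table()


@pytest.fixture(scope="session")
def membrane_params():
    return MembraneRestraintParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
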