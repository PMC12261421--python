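import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import orgnet as og

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_rigid_transform(rng: np.random.Generator):
    """A uniform random rotation and a translation of ~10 Å."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return rot, t


def apply_rigid(structure: og.Structure, rot: np.ndarray, t: np.ndarray) -> og.Structure:
    return structure.with_coords(structure.coords() @ rot.T + t)


@pytest.fixture(scope="session")
def helix() -> og.Structure:
    spec = og.PeptideSpec.regular("AKDWGS", phi=-57.0, psi=-47.0)
    return og.build_peptide(spec, "helix")


@pytest.fixture(scope="session")
def mutation_pair():
    """A WT/MT peptide pair with the mutation D3L mid-chain."""
    wt_spec = og.PeptideSpec.regular("AKDWGS", phi=-57.0, psi=-47.0)
    mt_spec = og.PeptideSpec.regular("AKLWGS", phi=-57.0, psi=-47.0)
    wt = og.build_peptide(wt_spec, "pair_wt")
    mt = og.build_peptide(mt_spec, "pair_mt")
    record = og.MutationRecord("pair_wt", "A", 3, "D", "L", ddg=1.2)
    return wt, mt, record


@pytest.fixture(scope="session")
def small_dataset() -> og.SyntheticDataset:
    return og.make_synthetic_dataset(8, seed=11)
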