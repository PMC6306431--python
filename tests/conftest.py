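import numpy as np
import pytest

from minorstate import synthetic
from minorstate.structures import StructureModel


@pytest.fixture(scope="session")
def noiseless_dispersion():
    """Six-residue two-field dataset with zero noise plus its ground truth."""
    cfg = synthetic.DispersionSimConfig(noise_sd=0.0, seed=1)
    dataset, truth = synthetic.gen_dispersion_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def hinge_set():
    cfg = synthetic.HingeSimConfig(seed=3)
    open_s, closed_s, target_s, info = synthetic.gen_hinge_structures(cfg)
    return open_s, closed_s, target_s, info, cfg


@pytest.fixture()
def toy_structure():
    """20-atom random cloud, dense enough to stay connected at 10 Å cutoff."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 9.0, size=(20, 3))
    n = len(coords)
    return StructureModel(
        chain=np.full(n, "A", dtype=object), resnum=np.arange(1, n + 1),
        resname=np.full(n, "GLY", dtype=object),
        atom_name=np.full(n, "CA", dtype=object),
        element=np.full(n, "C", dtype=object), coords=coords, source="toy")
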