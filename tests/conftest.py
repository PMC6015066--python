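import numpy as np
import pytest

from gnmflow.structures import ResidueNode, StructureModel
from gnmflow import build_kirchhoff, decompose, make_synthetic


def structure_from_coords(coords, source="test"):
    """Build a StructureModel directly from an (N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    nodes = [
        ResidueNode(chain_id="A", residue_number=i + 1, insertion_code="",
                    residue_name="GLY", position=coords[i], serial_index=i)
        for i in range(len(coords))
    ]
    return StructureModel(nodes=nodes, source=source)


def random_structure(seed, n=None, lo=4, hi=30):
    """Random self-avoiding-ish 3-D walk; consecutive steps < 7 A guarantee
    a connected contact network at the default cutoff, while chain
    re-approach creates nonlocal contacts."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(lo, hi + 1))
    steps = rng.uniform(3.0, 6.5, size=n - 1)
    dirs = rng.normal(size=(n - 1, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(dirs * steps[:, None], axis=0)])
    return structure_from_coords(coords, source=f"test:random:{seed}")


@pytest.fixture
def chain3():
    structure = make_synthetic("chain", 3, 5.0)
    kirchhoff = build_kirchhoff(structure, cutoff=7.0)
    return structure, kirchhoff, decompose(kirchhoff)


@pytest.fixture
def chain2():
    structure = make_synthetic("chain", 2, 5.0)
    kirchhoff = build_kirchhoff(structure, cutoff=7.0)
    return structure, kirchhoff, decompose(kirchhoff)
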