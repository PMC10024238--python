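import numpy as np
import pytest

from longiseg import mesh as meshmod
from longiseg.mesh import SimplexAtlas


@pytest.fixture(scope="session")
def toy_atlas_2d():
    return meshmod.make_toy_atlas((32, 32), k_classes=4, node_spacing=6.0)


@pytest.fixture(scope="session")
def toy_atlas_3d():
    return meshmod.make_toy_atlas((24, 24, 24), k_classes=4, node_spacing=6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_triangle_atlas(node_probs=None, grid_shape=(4, 4), stiffness=1.0):
    """Two triangles covering a small square grid."""
    positions = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0], [3.0, 3.0]])
    simplices = np.array([[0, 1, 3], [0, 3, 2]])
    if node_probs is None:
        node_probs = np.tile([0.5, 0.5], (4, 1))
    return SimplexAtlas(ref_positions=positions, simplices=simplices,
                        node_label_probs=np.asarray(node_probs, dtype=float),
                        stiffness=stiffness, grid_shape=grid_shape)


def perturbed(atlas, rng, amplitude=0.2):
    """Random unfolded perturbation of the atlas reference positions."""
    for _ in range(30):
        x = atlas.ref_positions + amplitude * rng.standard_normal(
            atlas.ref_positions.shape)
        if np.all(meshmod.signed_volumes(x, atlas.simplices) > 0):
            return x
        amplitude *= 0.7
    raise RuntimeError("could not build an unfolded perturbation")
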