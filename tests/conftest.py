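import numpy as np
import pytest

from micmac.segmentation import LabelVolume, SegmentationParams
from micmac.synthetic_data import CellSpec, SceneSpec, render_scene

#: Segmentation parameters matched to the default synthetic-scene imaging
#: model (PSF sigma 1 voxel, sparse foreground), mirroring the per-stack
#: parameter tuning the method prescribes for real acquisitions.
SCENE_SEG_PARAMS = SegmentationParams(
    saturation_fraction=0.002, psf_sigma=1.0, threshold_t=0.3
)

#: Spur-pruning threshold used when analysing rendered scenes: half the
#: minimum planted branch length, so thinning spurs are removed and real
#: terminal branches never are.
SCENE_SPUR_UM = 5.0


@pytest.fixture(scope="session")
def five_cell_scene():
    """One rendered 5-cell scene with ground truth (session-cached)."""
    specs = [CellSpec(seed=10 + s) for s in range(5)]
    stack, truth = render_scene(SceneSpec(seed=1), specs)
    return stack, truth


@pytest.fixture()
def ball_mask():
    """Digital ball of radius 10 µm at 1 µm isotropic voxels."""
    r = 10
    n = 2 * r + 5
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = n // 2
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    return mask


def make_label_volume(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> LabelVolume:
    return LabelVolume(labels=mask.astype(np.int32), voxel_size=voxel_size)
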