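"""Segment a synthetic 5-cell stack and compare against planted ground truth.

Renders branched tube cells into a noisy, unevenly lit 3D stack, runs the
five-stage slice-wise segmentation, and scores each planted cell's recovery
by Dice overlap. Dice near 1 means the recovered 3D mask almost coincides
with the planted cell.
"""

import numpy as np

from micmac.segmentation import SegmentationParams, segment_stack
from micmac.synthetic_data import CellSpec, SceneSpec, render_scene

specs = [CellSpec(seed=10 + s) for s in range(5)]
stack, truth = render_scene(SceneSpec(seed=1), specs)
print(f"rendered stack {stack.shape} voxels, {truth.labels.max()} planted cells")

params = SegmentationParams(saturation_fraction=0.002, psf_sigma=1.0, threshold_t=0.3)
label_volume = segment_stack(stack, params)
print(f"segmentation found {label_volume.n_labels} candidate objects")

for lab in range(1, truth.labels.max() + 1):
    planted = truth.labels == lab
    overlap = np.bincount(label_volume.labels[planted].ravel(), minlength=2)
    found = label_volume.labels == (overlap[1:].argmax() + 1)
    dice = 2 * np.logical_and(planted, found).sum() / (planted.sum() + found.sum())
    print(f"  cell {lab}: planted {planted.sum()} voxels, Dice = {dice:.3f}")
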