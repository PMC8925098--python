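"""Volumetric pathology load: percent of stack volume covered by a marker.

The score replaces an interactive surface-reconstruction workflow with an
equivalent open pipeline: Gaussian smoothing (the "surface detail" scale),
an absolute intensity threshold on the [0, 1] scale, 26-connected component
extraction, an optional minimum object volume, and finally

    percent = 100 * (sum of retained component volumes) / (stack volume).

One parameter set per marker is applied uniformly across cases and
subfields so scores are comparable within a marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .stack_io import ImageStack

__all__ = ["LoadParams", "LoadResult", "quantify_load"]


@dataclass(frozen=True)
class LoadParams:
    """Marker segmentation parameters for the volumetric load score.

    smoothing_sigma
        Gaussian sigma in voxels applied before thresholding; 0 disables
        smoothing, making the score the exact thresholded voxel fraction.
    threshold
        Absolute intensity threshold on [0, 1]; strictly-above is positive.
    min_object_volume
        Components smaller than this (µm³) are discarded as specks.
    """

    smoothing_sigma: float = 1.0
    threshold: float = 0.5
    min_object_volume: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.min_object_volume < 0:
            raise ValueError("min_object_volume must be >= 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass
class LoadResult:
    """Percent of stack volume covered by one marker in one acquisition."""

    case_id: str
    subfield: str
    marker: str
    percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError(f"percent out of range: {self.percent}")


def quantify_load(stack: ImageStack, params: LoadParams | None = None) -> LoadResult:
    """Compute the volumetric load score of one stack."""
    if params is None:
        params = LoadParams()
    img = stack.voxels
    if params.smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, params.smoothing_sigma, mode="nearest")
    positive = img > params.threshold
    if params.min_object_volume > 0 and positive.any():
        labels = measure.label(positive, connectivity=3)
        voxel_volume = stack.voxel_volume
        counts = np.bincount(labels.ravel())
        keep = np.nonzero(counts * voxel_volume >= params.min_object_volume)[0]
        keep = keep[keep != 0]
        positive = np.isin(labels, keep)
    percent = 100.0 * float(np.count_nonzero(positive)) / positive.size
    return LoadResult(
        case_id=stack.case_id,
        subfield=stack.subfield,
        marker=stack.channel,
        percent=percent,
    )
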