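"""End-to-end convenience: stack → gated cells → feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .artifact_filter import (
    BORDER_FRACTION_MAX,
    CellMask,
    border_gate,
    measure_all_cells,
    volume_gate,
)
from .morphograph import FEATURE_NAMES, build_graph, compute_features, skeletonize
from .segmentation import LabelVolume, SegmentationParams, segment_stack
from .stack_io import ImageStack

__all__ = ["extract_cells", "cells_to_table"]


def extract_cells(
    stack: ImageStack,
    params: SegmentationParams | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
    border_max: float = BORDER_FRACTION_MAX,
    label_volume: LabelVolume | None = None,
) -> tuple[LabelVolume, list[CellMask]]:
    """Segment a stack and return the gate-surviving cells.

    ``vmin``/``vmax`` default to the standard single-cell volume window;
    pass explicit bounds (or ``0``/``inf``) when working at other scales.
    """
    if label_volume is None:
        label_volume = segment_stack(stack, params)
    cells = measure_all_cells(label_volume)
    if vmin is not None or vmax is not None:
        from .artifact_filter import VOLUME_GATE_UM3

        cells = volume_gate(
            cells,
            vmin if vmin is not None else VOLUME_GATE_UM3[0],
            vmax if vmax is not None else VOLUME_GATE_UM3[1],
        )
    cells = border_gate(cells, border_max)
    return label_volume, cells


def cells_to_table(
    label_volume: LabelVolume,
    cells: list[CellMask],
    case_id: str = "",
    subfield: str = "other",
    condition: str = "",
    spur_min_length: float = 2.0,
) -> pd.DataFrame:
    """Skeletonize each cell, build its graph and tabulate the 16 features."""
    rows = []
    for cell in cells:
        mask = label_volume.labels == cell.label
        skel = skeletonize(mask, label_volume.voxel_size)
        graph = build_graph(skel, spur_min_length=spur_min_length)
        feats = compute_features(cell, graph)
        rows.append(
            {
                "case_id": case_id,
                "condition": condition,
                "subfield": subfield,
                "label": cell.label,
            }
            | feats
        )
    columns = ["case_id", "condition", "subfield", "label"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=columns)
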