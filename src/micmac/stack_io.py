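"""Calibrated 3D stack IO and cohort metadata.

Stacks are single-channel 3D grids with voxel sizes in micrometres, axis
order ``(z, y, x)``. All intensities are normalized to ``[0, 1]`` floats at
load time by dividing by the dtype maximum, so every downstream threshold is
defined on a unitless scale. The cohort table mirrors the demographic and
neuropathological metadata of a post-mortem case collection (diagnosis, sex,
age, post-mortem delay, staging).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "CalibrationError",
    "StackFormatError",
    "CohortValidationError",
    "read_stack",
    "write_stack",
    "read_cohort_table",
    "bundled_cohort_table",
    "default_analysis_groups",
]

SUBFIELDS = ("CA1", "CA3", "DG/CA4", "other")
DIAGNOSES = ("CTL", "AD", "DLB")


class CalibrationError(ValueError):
    """Voxel size unavailable from metadata and no override given."""


class StackFormatError(ValueError):
    """File is not a single-channel 3D grayscale stack."""


class CohortValidationError(ValueError):
    """Cohort metadata fails schema or uniqueness checks."""


@dataclass
class ImageStack:
    """One channel of a calibrated confocal stack.

    Parameters
    ----------
    voxels
        3D float array ``(z, y, x)`` of intensities in ``[0, 1]``.
    voxel_size
        Micrometres per voxel along ``(z, y, x)``.
    channel
        Marker label, e.g. ``"Iba1"``, ``"pTau"``, ``"Abeta"``, ``"pSyn"``.
    case_id, subfield
        Sample provenance used to key downstream tables.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""
    case_id: str = ""
    subfield: str = "other"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise StackFormatError(
                f"expected a 3D (z, y, x) stack, got ndim={self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise StackFormatError("stack contains non-finite intensities")
        if self.voxels.min() < 0:
            raise StackFormatError("stack contains negative intensities")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise CalibrationError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return float(np.prod(self.voxel_size))

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


def _rescale_to_unit(data: np.ndarray) -> np.ndarray:
    """Map raw intensities to [0, 1] by dividing by the dtype maximum.

    Monotone by construction; integer dtype max maps to exactly 1.0. Float
    inputs are assumed already on [0, 1] and only validated.
    """
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return data.astype(np.float64) / float(info.max)
    out = data.astype(np.float64)
    if out.size and (out.min() < 0 or out.max() > 1):
        raise StackFormatError("float stacks must already be scaled to [0, 1]")
    return out


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Recover (z, y, x) micrometre calibration from TIFF/OME-TIFF metadata."""
    if tif.ome_metadata:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None:
            try:
                return (
                    float(px.attrib["PhysicalSizeZ"]),
                    float(px.attrib["PhysicalSizeY"]),
                    float(px.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags and "YResolution" in tags:
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
        dx = xres[1] / xres[0] if xres[0] else None
        dy = yres[1] / yres[0] if yres[0] else None
        dz = None
        if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
            dz = float(tif.imagej_metadata["spacing"])
        if dx and dy and dz:
            return (dz, float(dy), float(dx))
    return None


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
    channel: str = "",
    case_id: str = "",
    subfield: str = "other",
) -> ImageStack:
    """Read a grayscale 3D TIFF/OME-TIFF into a calibrated :class:`ImageStack`.

    Voxel size is taken from OME or ImageJ/resolution metadata when present,
    otherwise from ``voxel_size_override``; absence of both is a
    :class:`CalibrationError`. Intensities are rescaled to [0, 1].
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_vs = _voxel_size_from_tiff(tif)
    if data.ndim == 2:
        raise StackFormatError(f"{path.name}: 2D image, expected a z-stack")
    if data.ndim != 3:
        raise StackFormatError(
            f"{path.name}: expected single-channel 3D data, got shape {data.shape}"
        )
    voxel_size = meta_vs if meta_vs is not None else voxel_size_override
    if voxel_size is None:
        raise CalibrationError(
            f"{path.name}: no voxel size in metadata and no override provided"
        )
    return ImageStack(
        voxels=_rescale_to_unit(data),
        voxel_size=tuple(voxel_size),
        channel=channel,
        case_id=case_id,
        subfield=subfield,
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with its micrometre calibration embedded."""
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        Path(path),
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def write_labels(labels: np.ndarray, voxel_size, path: str | Path) -> None:
    """Write an integer label volume as 32-bit TIFF."""
    dz, dy, dx = voxel_size
    tifffile.imwrite(
        Path(path),
        np.asarray(labels, dtype=np.int32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
        },
    )


_REQUIRED_COLUMNS = ("case_id", "diagnosis", "sex", "age", "pmd")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort metadata CSV.

    Required columns: case_id, diagnosis (CTL/AD/DLB), sex (M/F), age
    (years), pmd (hours). Optional: disease_score, concomitant, in_analysis
    (defaults to True). Raises :class:`CohortValidationError` on duplicate
    case ids, missing columns, or non-positive age/PMD.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"case_id": str})
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError(f"{path.name}: empty cohort file") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortValidationError(f"{path.name}: missing columns {missing}")
    if table.empty:
        raise CohortValidationError(f"{path.name}: cohort table has no rows")
    if table["case_id"].duplicated().any():
        dups = table.loc[table["case_id"].duplicated(), "case_id"].tolist()
        raise CohortValidationError(f"duplicate case ids: {dups}")
    for col in ("age", "pmd"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise CohortValidationError(f"column {col!r} must be positive numeric")
        table[col] = vals.astype(float)
    bad_dx = set(table["diagnosis"]) - set(DIAGNOSES)
    if bad_dx:
        raise CohortValidationError(f"unknown diagnosis values: {sorted(bad_dx)}")
    bad_sex = set(table["sex"]) - {"M", "F"}
    if bad_sex:
        raise CohortValidationError(f"unknown sex values: {sorted(bad_sex)}")
    if "in_analysis" not in table.columns:
        table["in_analysis"] = True
    else:
        table["in_analysis"] = (
            table["in_analysis"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
        )
    return table


def bundled_cohort_table() -> pd.DataFrame:
    """The bundled 30-case cohort fixture (11 CTL, 9 DLB, 10 AD)."""
    with importlib.resources.as_file(
        importlib.resources.files("micmac.data").joinpath("table1.csv")
    ) as p:
        return read_cohort_table(p)


def default_analysis_groups(table: pd.DataFrame) -> dict[str, list[str]]:
    """Analysis-group membership: per diagnosis, cases with in_analysis=True.

    The bundled cohort marks one DLB case (used for antibody validation, not
    image analysis) as excluded, giving groups of 11 CTL, 10 AD and 8 DLB —
    29 analyzed cases in total.
    """
    groups: dict[str, list[str]] = {}
    for dx in DIAGNOSES:
        sel = table[(table["diagnosis"] == dx) & table["in_analysis"]]
        groups[dx] = sel["case_id"].tolist()
    return groups
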