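"""Readers and writers for voxel volumes and analysis outputs.

Volumes are stored as multi-page TIFF stacks (or directories of per-slice
TIFFs in lexicographic order) with slices along array axis 0.  Anatomical
semantics live exclusively in the ``axis_map`` — never in storage order.
Voxel spacing is isotropic, given in micrometres, and is never guessed:
callers must supply it (typically from a JSON sidecar).

Physical coordinates are 0-based voxel-center coordinates:
``coordinate_um = index * spacing_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from ._axes import AxisMap, validate_axis_map

__all__ = [
    "FormatError",
    "VoxelVolume",
    "LabelMap",
    "read_volume_stack",
    "write_volume_stack",
    "export_field_csv",
    "FIELD_CSV_HEADER",
    "write_sidecar",
    "read_sidecar",
]

FIELD_CSV_HEADER = (
    "cx_um,cy_um,cz_um,e1x,e1y,e1z,e2x,e2y,e2z,e3x,e3y,e3z,"
    "l1_um,l2_um,l3_um,magnitude_um,anisotropy_index,material_fraction"
)


class FormatError(ValueError):
    """Raised for malformed volume stacks (e.g. inconsistent slice shapes)."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic spacing and an anatomical axis map."""

    data: np.ndarray
    spacing_um: float
    axis_map: AxisMap = ("X", "Y", "Z")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3D array")
        if self.spacing_um is None or self.spacing_um <= 0:
            raise ValueError("spacing_um must be a positive number")
        self.axis_map = validate_axis_map(self.axis_map)


@dataclass
class LabelMap:
    """An integer label grid with a legend mapping labels to tissue names."""

    labels: np.ndarray
    legend: dict
    spacing_um: float
    axis_map: AxisMap = ("X", "Y", "Z")

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if self.spacing_um is None or self.spacing_um <= 0:
            raise ValueError("spacing_um must be a positive number")
        self.axis_map = validate_axis_map(self.axis_map)
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels present but absent from legend: {sorted(missing)}")


def _read_stack_array(path: Path) -> np.ndarray:
    if path.is_dir():
        slices = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff")
        )
        if not slices:
            raise FormatError(f"no TIFF slices found in directory {path}")
        arrays = [tifffile.imread(p) for p in slices]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1 or arrays[0].ndim != 2:
            raise FormatError(
                f"slice shapes are inconsistent in {path}: {sorted(shapes)}"
            )
        return np.stack(arrays, axis=0)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D/3D TIFF stack, got shape {data.shape}")
    return data


def read_volume_stack(
    path,
    spacing_um: float,
    axis_map=("X", "Y", "Z"),
    legend: Optional[dict] = None,
):
    """Read a multi-page TIFF (or slice directory) into a volume.

    Slices are stacked along array axis 0.  Passing a ``legend`` with
    integer-typed data yields a :class:`LabelMap`, otherwise a
    :class:`VoxelVolume`.  Spacing must always be supplied.
    """
    if spacing_um is None:
        raise ValueError("spacing_um is required; voxel spacing is never guessed")
    data = _read_stack_array(Path(path))
    if legend is not None:
        if not np.issubdtype(data.dtype, np.integer):
            raise FormatError("a legend was given but the stack is not integer-typed")
        return LabelMap(labels=data, legend=legend, spacing_um=spacing_um,
                        axis_map=axis_map)
    return VoxelVolume(data=data, spacing_um=spacing_um, axis_map=axis_map)


def write_volume_stack(volume, path) -> None:
    """Write a volume as a lossless multi-page TIFF, slices along axis 0.

    Boolean data is stored as 8-bit {0, 1}; integers keep their dtype;
    floats are stored as 32-bit.
    """
    data = volume.labels if isinstance(volume, LabelMap) else volume.data
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, data, photometric="minisblack")


def _fmt(x: float) -> str:
    return f"{float(x):.9g}"


def export_field_csv(field, path) -> None:
    """Export an orientation field as CSV: one row per retained window.

    Columns are the window center (um, anatomical frame), the three
    canonicalized eigenvectors, the length-scale eigenvalues, the magnitude
    (primary eigenvalue), the anisotropy index, and the window material
    fraction.  Floats carry 9 significant digits; rows are ordered by window
    grid index (anatomical Z-major, then Y, then X); comma separator, UNIX
    newlines, '.' decimal, no quoting.
    """
    lines = [FIELD_CSV_HEADER]
    for s in field.samples:
        values = [
            *s.center_um, *s.e1, *s.e2, *s.e3, *s.eigenvalues_um,
            s.magnitude_um, s.anisotropy, s.material_fraction,
        ]
        lines.append(",".join(_fmt(v) for v in values))
    Path(path).write_bytes(("\n".join(lines) + "\n").encode("ascii"))


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON sidecar (spacing, axis map, legend, phantom truth...)."""
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
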