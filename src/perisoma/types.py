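"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Label volumes are integer arrays indexed ``[x, y, z]`` with an anisotropic
  voxel resolution in nanometres (reference resolution 64 x 64 x 40 nm) and a
  spatial offset, so voxel ``(i, j, k)`` has its centre at
  ``offset_nm + (i + 0.5, j + 0.5, k + 0.5) * resolution_nm``.
* Meshes are :class:`trimesh.Trimesh` objects with vertices in nanometres in
  volume (world) coordinates.
* Synapse tables are :class:`pandas.DataFrame` objects with the columns in
  :data:`SYNAPSE_COLUMNS`: presynaptic segment id, postsynaptic segment id,
  location in nm and predicted size in voxels.
* The depth axis follows image-style coordinates: depth increases along the
  configured axis (``y`` by default), with the pial surface at the configured
  coordinate.  Depths are reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a synapse table.
SYNAPSE_COLUMNS = ("pre_id", "post_id", "x_nm", "y_nm", "z_nm", "size_vx")

#: Axis names usable for the depth/sectioning axes.
AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class LabeledVolume:
    """A 3-D integer label grid with voxel resolution (nm) and offset (nm)."""

    data: np.ndarray
    resolution_nm: tuple[float, float, float]
    offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        res = np.asarray(self.resolution_nm, dtype=float)
        if res.shape != (3,) or np.any(res <= 0):
            raise ValueError("resolution_nm must be three positive numbers")
        self.resolution_nm = tuple(res)
        self.offset_nm = tuple(np.asarray(self.offset_nm, dtype=float))

    @property
    def voxel_volume_nm3(self) -> float:
        return float(np.prod(self.resolution_nm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, xyz_nm: np.ndarray) -> np.ndarray:
        """Convert world coordinates (nm) to fractional voxel indices."""
        xyz_nm = np.asarray(xyz_nm, dtype=float)
        return (xyz_nm - np.asarray(self.offset_nm)) / np.asarray(self.resolution_nm)

    def voxel_centers_nm(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (nm) of the centres of the given voxel indices."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.offset_nm) + (idx + 0.5) * np.asarray(self.resolution_nm)


@dataclass
class DepthReference:
    """Flat-pia depth convention: a plane normal to one axis.

    ``depth_axis`` names the axis along which cortical depth increases
    (pia -> white matter); ``pia_coordinate_nm`` is the world coordinate of the
    pial surface on that axis.
    """

    depth_axis: str = "y"
    pia_coordinate_nm: float = 0.0

    @property
    def axis(self) -> int:
        return AXIS_INDEX[self.depth_axis]

    def depth_um(self, xyz_nm: np.ndarray) -> np.ndarray:
        """Cortical depth (um) of world points."""
        xyz_nm = np.atleast_2d(np.asarray(xyz_nm, dtype=float))
        return (xyz_nm[:, self.axis] - self.pia_coordinate_nm) / 1000.0

    def depth_direction(self) -> np.ndarray:
        """Unit vector pointing from pia toward white matter."""
        d = np.zeros(3)
        d[self.axis] = 1.0
        return d


def validate_synapse_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a synapse table for the documented columns."""
    missing = [c for c in SYNAPSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"synapse table missing columns: {missing}")
    return table


def synapse_xyz(table: pd.DataFrame) -> np.ndarray:
    """(n, 3) array of synapse locations in nm."""
    return table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)


def empty_synapse_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float if "nm" in c else int)
                         for c in SYNAPSE_COLUMNS})
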