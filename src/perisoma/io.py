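"""File formats: HDF5 label volumes, PLY meshes, CSV synapse/feature tables.

Label volumes are stored as an HDF5 dataset ``labels`` with attributes
``resolution_nm`` and ``offset_nm``.  Synapse CSVs carry the documented
columns pre_id, post_id, x_nm, y_nm, z_nm, size_vx.  Feature tables are CSVs
indexed by cell_id.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .types import LabeledVolume, SYNAPSE_COLUMNS, validate_synapse_table


def save_volume(path, volume: LabeledVolume) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("labels", data=volume.data, compression="gzip")
        ds.attrs["resolution_nm"] = np.asarray(volume.resolution_nm)
        ds.attrs["offset_nm"] = np.asarray(volume.offset_nm)


def load_volume(path) -> LabeledVolume:
    with h5py.File(path, "r") as f:
        ds = f["labels"]
        return LabeledVolume(
            data=ds[...],
            resolution_nm=tuple(ds.attrs["resolution_nm"]),
            offset_nm=tuple(ds.attrs.get("offset_nm", (0.0, 0.0, 0.0))),
        )


def save_mesh(path, mesh: trimesh.Trimesh) -> None:
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


def load_mesh(path) -> trimesh.Trimesh:
    return trimesh.load(str(path), force="mesh")


def save_synapses(path, table: pd.DataFrame) -> None:
    validate_synapse_table(table)
    table[list(SYNAPSE_COLUMNS)].to_csv(path, index=False)


def load_synapses(path) -> pd.DataFrame:
    return validate_synapse_table(pd.read_csv(path))


def save_features(path, table: pd.DataFrame) -> None:
    if table.index.name != "cell_id":
        raise ValueError("feature table must be indexed by cell_id")
    table.to_csv(path)


def load_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")
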