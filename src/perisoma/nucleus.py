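"""Nucleus morphometry: mesh extraction, shrink-wrap infolding quantification
and the six nucleus features.

Neuronal nuclei form membrane infoldings (invaginations).  They are quantified
by building an outer *shrink-wrap* envelope that bridges the mouths of the
invaginations and measuring, for every nucleus vertex, the unsigned distance
to that envelope: any vertex further than 150 nm is considered to be within an
infolding, and the folded surface area is accumulated over faces whose three
vertices all exceed the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

from .types import DepthReference, LabeledVolume
from .meshutil import MeshProximity, largest_component, vertex_neighbor_means

#: fold detection depth (nm): vertices further than this from the wrap are
#: inside an infolding (strict >)
FOLD_THRESHOLD_NM = 150.0


@dataclass
class NucleusFeatures:
    """The six nucleus features."""

    volume_um3: float
    area_um2: float
    area_to_volume: float        # 1/um
    fold_area_um2: float
    fold_fraction: float
    depth_um: float

    def as_dict(self) -> dict[str, float]:
        return {
            "nucleus_volume_um3": self.volume_um3,
            "nucleus_area_um2": self.area_um2,
            "nucleus_area_to_volume": self.area_to_volume,
            "nucleus_fold_area_um2": self.fold_area_um2,
            "nucleus_fold_fraction": self.fold_fraction,
            "depth_um": self.depth_um,
        }


def mesh_from_label(volume: LabeledVolume, label: int) -> trimesh.Trimesh:
    """Marching-cubes isosurface of one label, largest component only.

    Vertices are in nm in volume (world) coordinates.
    """
    mask = volume.data == label
    if not mask.any():
        raise ValueError(f"label {label} not present in volume")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=volume.resolution_nm)
    # undo the one-voxel pad, shift to voxel-centre world coordinates
    verts = verts - np.asarray(volume.resolution_nm) * 0.5 + np.asarray(volume.offset_nm)
    # marching-cubes winding is inward for label masks; flip to outward normals
    mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=True)
    return largest_component(mesh)


def shrink_wrap(mesh: trimesh.Trimesh,
                target_edge_nm: float | None = None,
                snap_tol_nm: float = 25.0) -> trimesh.Trimesh:
    """Outer envelope of a mesh that spans the mouths of invaginations.

    The envelope is the convex hull, subdivided to roughly the input edge
    scale, with a single projection pass: wrap vertices already within
    ``snap_tol_nm`` of the input surface snap exactly onto it, while vertices
    bridging an invagination mouth (far from the surface) are left on the
    hull.  The projection is one-shot and snap-only by design: any iterative
    attraction of bridge vertices lets the membrane creep down the steep
    walls of an infolding, which corrupts the per-vertex fold distances.

    Guarantees (up to the chordal error of the triangulation): every input
    vertex lies inside or on the wrap, wrap volume >= input volume, the wrap
    of a convex mesh reproduces the mesh, and wrapping is idempotent.  A
    shallow concavity of the whole nucleus (as opposed to an infolding) is
    bridged as well; this conservative behaviour is documented in the
    methods note.
    """
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError("cannot wrap an empty mesh")
    if not mesh.is_watertight:
        mesh = mesh.copy()
        trimesh.repair.fill_holes(mesh)
        if not mesh.is_watertight:
            raise ValueError("mesh is not watertight and could not be repaired")

    hull = mesh.convex_hull
    if target_edge_nm is None:
        target_edge_nm = 4.0 * float(mesh.edges_unique_length.mean())
    verts, faces = trimesh.remesh.subdivide_to_size(
        hull.vertices, hull.faces, max_edge=target_edge_nm, max_iter=6)
    wrap = trimesh.Trimesh(vertices=verts, faces=faces, process=True)

    closest, dist, _ = MeshProximity(mesh).closest(wrap.vertices)
    snapped = dist <= snap_tol_nm
    verts = wrap.vertices.copy()
    verts[snapped] = closest[snapped]
    return trimesh.Trimesh(vertices=verts, faces=wrap.faces.copy(), process=False)


def fold_features(mesh: trimesh.Trimesh, wrap: trimesh.Trimesh,
                  threshold_nm: float = FOLD_THRESHOLD_NM) -> tuple[float, float]:
    """(fold_area_um2, fold_fraction) of a nucleus mesh against its wrap.

    Per-vertex unsigned nearest-point distance to the wrap surface; each face
    contributes its area in proportion to how many of its three vertices
    exceed the threshold strictly (barycentric accounting).  An all-or-
    nothing face rule is biased low on steep-walled folds, where the boundary
    ring consists of strongly stretched faces; the proportional rule is
    unbiased and still accounts area per-face.
    """
    _check_wrap_pair(mesh, wrap)
    _, dist, _ = MeshProximity(wrap).closest(mesh.vertices)
    folded_vertex = dist > threshold_nm
    frac_folded = folded_vertex[mesh.faces].sum(axis=1) / 3.0
    fold_area_nm2 = float((mesh.area_faces * frac_folded).sum())
    total_nm2 = float(mesh.area)
    if total_nm2 <= 0:
        raise ValueError("degenerate mesh: zero surface area")
    return fold_area_nm2 / 1e6, fold_area_nm2 / total_nm2


def _check_wrap_pair(mesh: trimesh.Trimesh, wrap: trimesh.Trimesh) -> None:
    """Cheap sanity check that `wrap` plausibly envelopes `mesh`."""
    if wrap.is_empty or mesh.is_empty:
        raise ValueError("empty mesh/wrap pair")
    try:
        v_mesh, v_wrap = abs(mesh.volume), abs(wrap.volume)
    except Exception:  # pragma: no cover - malformed topology
        raise ValueError("mismatched mesh/wrap pair")
    if v_wrap < 0.95 * v_mesh:
        raise ValueError("wrap volume smaller than mesh volume: mismatched pair")
    lo = wrap.bounds[0] - 0.05 * (wrap.bounds[1] - wrap.bounds[0])
    hi = wrap.bounds[1] + 0.05 * (wrap.bounds[1] - wrap.bounds[0])
    if (mesh.bounds[0] < lo).any() or (mesh.bounds[1] > hi).any():
        raise ValueError("mesh extends outside wrap bounds: mismatched pair")


def nucleus_features(mesh: trimesh.Trimesh,
                     depth_reference: DepthReference,
                     wrap: trimesh.Trimesh | None = None,
                     threshold_nm: float = FOLD_THRESHOLD_NM) -> NucleusFeatures:
    """All six nucleus features; the wrap is computed if not supplied."""
    if mesh.is_empty or mesh.area <= 0:
        raise ValueError("degenerate mesh")
    if wrap is None:
        wrap = shrink_wrap(mesh)
    fold_area, fold_fraction = fold_features(mesh, wrap, threshold_nm)
    volume_um3 = abs(float(mesh.volume)) / 1e9
    area_um2 = float(mesh.area) / 1e6
    if volume_um3 <= 0:
        raise ValueError("degenerate mesh: zero volume")
    centroid = mesh.center_mass if mesh.is_watertight else mesh.vertices.mean(axis=0)
    depth = float(depth_reference.depth_um(centroid)[0])
    return NucleusFeatures(
        volume_um3=volume_um3,
        area_um2=area_um2,
        area_to_volume=area_um2 / volume_um3,
        fold_area_um2=fold_area,
        fold_fraction=fold_fraction,
        depth_um=depth,
    )
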