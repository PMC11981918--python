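"""Mesh geometry primitives: closest-point queries, surface sampling and
local-thickness estimation.

These are deliberately dependency-light (numpy/scipy/trimesh only) and
vectorized, since spatial-index backends are not assumed to be present.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# point / triangle distance


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point (paired).

    Parameters
    ----------
    points : (m, 3)
    triangles : (m, 3, 3)

    Returns
    -------
    (m, 3) closest points.
    """
    p = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]

    # Ericson, "Real-Time Collision Detection", closest point on triangle.
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), c)
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))
    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class MeshProximity:
    """Approximate-candidate exact closest-point queries against a mesh.

    Candidate faces come from a KD-tree over face centroids (k nearest, with k
    scaled up when triangles are large relative to their spacing); the exact
    point-triangle distance is then evaluated on candidates only.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 12):
        self.mesh = mesh
        self.k = min(int(k), len(mesh.faces))
        self._centroids = mesh.triangles_center
        self._tree = cKDTree(self._centroids)
        self._triangles = mesh.triangles

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, face indices) for query points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(pts, k=self.k)
        cand = np.atleast_2d(cand)
        m, k = cand.shape
        flat_pts = np.repeat(pts, k, axis=0)
        flat_tris = self._triangles[cand.ravel()]
        closest = closest_point_on_triangles(flat_pts, flat_tris)
        d2 = np.einsum("ij,ij->i", flat_pts - closest, flat_pts - closest)
        d2 = d2.reshape(m, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(m)
        closest = closest.reshape(m, k, 3)[rows, best]
        faces = cand[rows, best]
        return closest, np.sqrt(d2[rows, best]), faces


def closest_point_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray,
                          k: int = 12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-shot convenience wrapper around :class:`MeshProximity`."""
    return MeshProximity(mesh, k=k).closest(points)


# ---------------------------------------------------------------------------
# sampling and pose


def sample_surface(mesh: trimesh.Trimesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform sample of n points on the mesh surface."""
    if n <= 0:
        raise ValueError("n must be positive")
    areas = mesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate mesh: zero surface area")
    face_idx = rng.choice(len(areas), size=n, p=areas / total)
    tri = mesh.triangles[face_idx]
    # uniform barycentric coordinates
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    u = 1.0 - r1
    v = r1 * (1.0 - r2)
    w = r1 * r2
    return u[:, None] * tri[:, 0] + v[:, None] * tri[:, 1] + w[:, None] * tri[:, 2]


def vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Barycentric vertex areas (1/3 of each incident face area)."""
    va = np.zeros(len(mesh.vertices))
    np.add.at(va, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return va


def vertex_neighbor_means(mesh_vertices: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean position of the 1-ring neighbours of every vertex."""
    n = len(mesh_vertices)
    sums = np.zeros((n, 3))
    counts = np.zeros(n)
    i, j = edges[:, 0], edges[:, 1]
    np.add.at(sums, i, mesh_vertices[j])
    np.add.at(sums, j, mesh_vertices[i])
    np.add.at(counts, i, 1.0)
    np.add.at(counts, j, 1.0)
    counts = np.maximum(counts, 1.0)
    return sums / counts[:, None]


# ---------------------------------------------------------------------------
# local thickness (shape diameter) via shrinking maximal inscribed balls


def local_diameter(mesh: trimesh.Trimesh, points: np.ndarray,
                   inward_normals: np.ndarray, r_max: float,
                   n_iter: int = 10) -> np.ndarray:
    """Local shape diameter at surface points by the shrinking-ball method.

    A ball tangent at each point (centre along the inward normal) is shrunk
    until it is maximally inscribed; the local diameter is twice its radius.
    For a cylinder of radius R this yields 2R, matching a ray-cast chord
    through the shaft.  Radii are capped at ``r_max`` (open meshes, e.g. soma
    patches, never converge below their curvature radius).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n_in = np.atleast_2d(np.asarray(inward_normals, dtype=float))
    n_in = n_in / np.linalg.norm(n_in, axis=1, keepdims=True)
    prox = MeshProximity(mesh, k=min(16, len(mesh.faces)))
    r = np.full(len(p), float(r_max))
    eps = 1e-9
    for _ in range(n_iter):
        centers = p + r[:, None] * n_in
        x, d_cx, _ = prox.closest(centers)
        diff = p - x
        d2 = np.einsum("ij,ij->i", diff, diff)
        denom = 2.0 * np.einsum("ij,ij->i", -diff, n_in)  # 2 * n_in . (x - p)
        # a contact only counts if it is meaningfully inside the current ball
        # (discretization ridges otherwise shrink r without bound) and lies
        # genuinely inward of p's tangent plane (curvature noise guard)
        penetrating = d_cx < (1.0 - 0.02) * r
        inward = np.einsum("ij,ij->i", -diff, n_in) > 0.2 * np.sqrt(d2)
        valid = (denom > eps) & (d2 > eps) & inward & penetrating
        new_r = np.where(valid, d2 / np.maximum(denom, eps), r)
        r = np.where(new_r < r - 1e-6, new_r, r)
    return 2.0 * np.clip(r, 0.0, r_max)


def largest_component(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Largest connected component of a mesh, by absolute enclosed volume,
    falling back to surface area for open fragments."""
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    scores = []
    for part in parts:
        vol = abs(part.volume) if part.is_watertight else 0.0
        scores.append((vol, part.area))
    best = max(range(len(parts)), key=lambda i: scores[i])
    return parts[best]
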