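"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own geometry/statistics code paths:
ray casting is plain Moller-Trumbore over every triangle, closest points are
all-pairs scans, and the Fisher p-value is a full hypergeometric enumeration.
"""

from __future__ import annotations

import numpy as np
from math import lgamma, exp


def ray_mesh_intersections(origin, direction, mesh) -> np.ndarray:
    """Sorted positive hit distances of a single ray against every triangle."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    mask = np.abs(a) > 1e-12
    f = np.zeros_like(a)
    f[mask] = 1.0 / a[mask]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ d)
    t = f * np.einsum("ij,ij->i", q, e2)
    hit = mask & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-6)
    return np.sort(t[hit])


def chord_thickness(point, inward_direction, mesh, cone_deg: float = 0.0,
                    n_rays: int = 5) -> float:
    """Ray-cast diameter at a surface point: the chord along the inward
    direction or, with ``cone_deg`` > 0, the minimum chord over a small cone
    of rays (which suppresses oblique-exit artefacts near end caps)."""
    d0 = np.asarray(inward_direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)
    directions = [d0]
    if cone_deg > 0:
        # two orthogonal tangents
        t1 = np.cross(d0, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(d0, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(d0, t1)
        ang = np.radians(cone_deg)
        for i in range(n_rays - 1):
            psi = 2 * np.pi * i / (n_rays - 1)
            d = (np.cos(ang) * d0
                 + np.sin(ang) * (np.cos(psi) * t1 + np.sin(psi) * t2))
            directions.append(d)
    chords = []
    for d in directions:
        hits = ray_mesh_intersections(np.asarray(point) + 1e-3 * d, d, mesh)
        if len(hits):
            chords.append(hits[0])
    return float(min(chords)) if chords else np.inf


def brute_force_closest(points, mesh) -> np.ndarray:
    """Exact closest distances by scanning every triangle (small meshes)."""
    from perisoma.meshutil import closest_point_on_triangles

    out = np.empty(len(points))
    tri = mesh.triangles
    for i, p in enumerate(np.atleast_2d(points)):
        cp = closest_point_on_triangles(np.repeat(p[None], len(tri), axis=0), tri)
        out[i] = np.linalg.norm(cp - p, axis=1).min()
    return out


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_two_tailed_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-tailed Fisher p by enumerating all tables with the observed
    margins and summing point probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(x: int) -> float:
        return (_log_comb(r1, x) + _log_comb(r2, c1 - x) - _log_comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= p_obs + 1e-9:
            total += exp(lp)
    return min(total, 1.0)
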