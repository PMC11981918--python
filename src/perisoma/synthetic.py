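"""Phantom generators with analytically known ground truth.

Every downstream stage (nucleus morphometry, soma cleanup, postsynaptic-shape
extraction, the classifier cascade and the connectivity statistics) is
exercised against volumes, meshes, synapse tables and cohorts produced here,
so each generator returns the quantity it planted alongside the data.

All randomness flows from a single integer seed through
:func:`numpy.random.SeedSequence` spawn keys, so sub-generators are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .types import LabeledVolume, SYNAPSE_COLUMNS, empty_synapse_table
from .meshutil import vertex_areas

#: Canonical feature column names used by cohorts and the classifier cascade.
NUCLEUS_FEATURE_NAMES = (
    "nucleus_volume_um3",
    "nucleus_area_um2",
    "nucleus_area_to_volume",
    "nucleus_fold_area_um2",
    "nucleus_fold_fraction",
    "depth_um",
)
SOMA_FEATURE_NAMES = (
    "soma_volume_um3",
    "soma_area_um2",
    "soma_area_to_volume",
    "soma_synapse_count",
    "soma_synapse_density",
    "nucleus_to_soma_volume_ratio",
    "centroid_offset_um",
)


def pss_column_names(n_shapes: int = 30, n_radial: int = 4) -> list[str]:
    """Column names of the flattened (row-major: shape, then radial bin)
    spatial shape histogram."""
    return [f"pss_{c:02d}_{b}" for c in range(n_shapes) for b in range(n_radial)]


def split_rng(seed: int, *keys: int) -> np.random.Generator:
    """Counter-based seed splitting: independent stream per key tuple."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(keys)))


# ---------------------------------------------------------------------------
# nucleus phantoms


@dataclass
class NucleusPhantomSpec:
    """Specification of a spherical nucleus phantom with planted infoldings.

    Invaginations are radial inward dimples: a flat floor displaced by
    ``fold_depth_nm``, joined to the undeformed sphere by a narrow smoothstep
    rim.  The planted (true) folded-area fraction is the vertex-area fraction
    whose inward displacement exceeds the 150 nm detection depth, evaluated on
    the undeformed parameterization, so it is exact by construction.
    """

    radius_um: float = 5.0
    n_folds: int = 0
    fold_depth_nm: float = 1500.0
    fold_area_fraction: float = 0.2
    mesh_resolution_nm: float = 200.0
    seed: int = 0
    #: depth (nm) beyond which a vertex counts as inside a fold
    detection_depth_nm: float = 150.0
    #: if True (default), the dimple cap angle is calibrated by quadrature so
    #: that the *deformed-surface* area fraction displaced beyond the
    #: detection depth equals ``fold_area_fraction`` (fold walls gain area
    #: while the floor loses it; the calibration accounts for both).  If
    #: False, the cap is sized on the undeformed sphere, so deeper folds
    #: yield larger true deformed-area fractions at a fixed requested value.
    calibrate: bool = True

    def validate(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.fold_area_fraction <= 1.0:
            raise ValueError("fold_area_fraction must be in [0, 1]")
        if self.n_folds < 0:
            raise ValueError("n_folds must be non-negative")
        if self.n_folds > 0:
            if self.fold_depth_nm <= self.detection_depth_nm:
                raise ValueError("fold_depth_nm must exceed the detection depth")
            if self.fold_depth_nm >= self.radius_um * 1000.0:
                raise ValueError("fold_depth_nm must be smaller than the radius")
        if self.mesh_resolution_nm <= 0:
            raise ValueError("mesh_resolution_nm must be positive")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _smoothstep_inverse(y: float) -> float:
    """Inverse of 3t^2 - 2t^3 on [0, 1] by bisection."""
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _smoothstep(np.array(mid)) < y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _fold_profile_params(spec: "NucleusPhantomSpec", ang_c: float) -> tuple[float, float, float]:
    """Rim geometry for a dimple whose displacement crosses the detection
    depth exactly at polar angle ``ang_c``: returns (rim width, a0, a1)."""
    radius_nm = spec.radius_um * 1000.0
    rim_w = max(0.12 * ang_c, 2.5 * spec.mesh_resolution_nm / radius_nm)
    t_star = _smoothstep_inverse(spec.detection_depth_nm / spec.fold_depth_nm)
    a1 = ang_c + rim_w * t_star
    return rim_w, a1 - rim_w, a1


def _deformed_area_fraction(spec: "NucleusPhantomSpec", ang_c: float,
                            n_grid: int = 4000) -> float:
    """Deformed-surface area fraction displaced beyond the detection depth,
    by quadrature on the surface-of-revolution meridian of one dimple."""
    R = spec.radius_um * 1000.0
    rim_w, _, a1 = _fold_profile_params(spec, ang_c)
    theta = np.linspace(0.0, a1, n_grid)
    disp = spec.fold_depth_nm * _smoothstep((a1 - theta) / rim_w)
    r = R - disp
    dr = np.gradient(r, theta)
    # dA = 2 pi (r sin theta) sqrt(r'^2 + r^2) dtheta for a meridian r(theta)
    integrand = 2.0 * np.pi * (r * np.sin(theta)) * np.sqrt(dr * dr + r * r)
    flagged = disp > spec.detection_depth_nm
    area_fold = np.trapezoid(np.where(flagged, integrand, 0.0), theta)
    area_dimple = np.trapezoid(integrand, theta)
    sphere_outside = 4.0 * np.pi * R * R - spec.n_folds * 2.0 * np.pi * R * R * (1 - np.cos(a1))
    total = sphere_outside + spec.n_folds * area_dimple
    return spec.n_folds * area_fold / total


def _calibrated_cap_angle(spec: "NucleusPhantomSpec") -> float:
    """Cap angle whose deformed flagged-area fraction matches the request."""
    from scipy.optimize import brentq

    target = spec.fold_area_fraction / 1.0
    lo, hi = 0.02, float(np.arccos(1.0 - 2.0 * 0.45 / spec.n_folds))

    def f(a):
        return _deformed_area_fraction(spec, a) - target

    if f(hi) < 0:
        raise ValueError("fold_area_fraction too large for this fold geometry")
    if f(lo) > 0:
        raise ValueError("fold_area_fraction too small to resolve")
    return float(brentq(f, lo, hi, xtol=1e-6))


def _fold_directions(n: int, min_separation: float, rng: np.random.Generator) -> np.ndarray:
    """Random unit vectors with a minimum pairwise angular separation."""
    dirs: list[np.ndarray] = []
    for _ in range(20000):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.arccos(np.clip(v @ d, -1, 1)) > min_separation for d in dirs):
            dirs.append(v)
            if len(dirs) == n:
                return np.array(dirs)
    raise ValueError(
        f"could not place {n} folds with separation {np.degrees(min_separation):.1f} deg; "
        "reduce n_folds or fold_area_fraction")


def make_nucleus_phantom(spec: NucleusPhantomSpec) -> tuple[trimesh.Trimesh, float]:
    """Build a nucleus phantom and return it with its true folded-area fraction."""
    spec.validate()
    radius_nm = spec.radius_um * 1000.0
    # icosphere subdivision level from the requested edge length
    edge0 = 1.0515 * radius_nm  # icosahedron edge for a unit-ish sphere
    subdiv = int(np.clip(np.ceil(np.log2(edge0 / spec.mesh_resolution_nm)), 2, 7))
    sphere = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius_nm)

    if spec.n_folds == 0 or spec.fold_area_fraction == 0.0:
        if not sphere.is_watertight:
            raise RuntimeError("phantom generation produced a non-watertight mesh")
        return sphere, 0.0

    rng = split_rng(spec.seed, 0)
    cap_fraction = spec.fold_area_fraction / spec.n_folds
    if cap_fraction >= 0.5:
        raise ValueError("per-fold cap fraction must be < 0.5")
    if spec.calibrate:
        ang_c = _calibrated_cap_angle(spec)
    else:
        # spherical cap of area fraction f has half-angle arccos(1 - 2 f)
        ang_c = float(np.arccos(1.0 - 2.0 * cap_fraction))
    rim_w, a0, a1 = _fold_profile_params(spec, ang_c)
    if a0 <= 0:
        raise ValueError("fold cap too small for the rim width; enlarge fold_area_fraction")

    dirs = _fold_directions(spec.n_folds, min_separation=2.2 * a1, rng=rng)

    verts = sphere.vertices.copy()
    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    ang = np.arccos(np.clip(unit @ dirs.T, -1.0, 1.0))  # (n_verts, n_folds)
    profile = _smoothstep((a1 - ang) / rim_w)           # 1 inside floor, 0 outside
    disp = spec.fold_depth_nm * profile.max(axis=1)

    deformed = trimesh.Trimesh(
        vertices=verts - unit * disp[:, None],
        faces=sphere.faces.copy(),
        process=False,
    )
    # patch-area oracle: flag vertices by their planted displacement, account
    # membrane area on the generated (deformed) surface
    va = vertex_areas(deformed)
    true_fraction = float(va[disp > spec.detection_depth_nm].sum() / va.sum())

    if not deformed.is_watertight:
        raise RuntimeError("phantom generation produced a non-watertight mesh")
    return deformed, true_fraction


# ---------------------------------------------------------------------------
# labelled cell volumes


def _sphere_mask(shape: tuple[int, int, int], center_nm: np.ndarray,
                 radius_nm: float, resolution_nm: np.ndarray) -> np.ndarray:
    """Point-in-sphere test at voxel centres (z-chunked to bound memory)."""
    nx, ny, nz = shape
    xs = (np.arange(nx) + 0.5) * resolution_nm[0] - center_nm[0]
    ys = (np.arange(ny) + 0.5) * resolution_nm[1] - center_nm[1]
    zs = (np.arange(nz) + 0.5) * resolution_nm[2] - center_nm[2]
    mask = np.zeros(shape, dtype=bool)
    r2 = radius_nm * radius_nm
    xy2 = xs[:, None] ** 2 + ys[None, :] ** 2
    chunk = max(1, int(2e8 // (nx * ny)))
    for k0 in range(0, nz, chunk):
        k1 = min(nz, k0 + chunk)
        mask[:, :, k0:k1] = xy2[:, :, None] + zs[None, None, k0:k1] ** 2 <= r2
    return mask


def make_cell_volume(
    nucleus_spec: NucleusPhantomSpec,
    soma_radius_um: float = 8.0,
    n_soma_synapses: int = 20,
    error_void_fraction: float = 0.0,
    resolution_nm: tuple[float, float, float] = (64.0, 64.0, 40.0),
    seed: int = 0,
    half_width_um: float = 10.0,
    soma_label: int = 2,
    background_label: int = 1,
    nucleus_label: int = 1,
    gap_slab: tuple[int, int] | None = None,
    fragment: tuple[tuple[int, int, int], int] | None = None,
) -> tuple[LabeledVolume, LabeledVolume, pd.DataFrame]:
    """Voxelized concentric nucleus-in-soma phantom with surface synapses.

    Label 0 is reserved for error/void.  ``error_void_fraction`` of the voxels
    in the (up to) 15 um bounding box around the nucleus centre are set to 0,
    drawn from background voxels only.  ``gap_slab=(k0, thickness)`` blanks a
    z-slab of the soma (simulated lost sections); ``fragment=(offset_vx, n)``
    plants a detached run of ``n`` soma-labelled voxels at the given voxel
    offset from the centre (simulated merged fragment).

    The nucleus is rasterized as a sphere of the spec radius; the planted
    infoldings of :func:`make_nucleus_phantom` are a mesh-level construct and
    are below the relevance of the voxel-level tests this phantom serves.
    """
    nucleus_spec.validate()
    if soma_radius_um <= nucleus_spec.radius_um:
        raise ValueError("soma radius must exceed the nucleus radius")
    if half_width_um < soma_radius_um:
        raise ValueError("volume too small to contain the soma")
    if not 0.0 <= error_void_fraction < 1.0:
        raise ValueError("error_void_fraction must be in [0, 1)")

    res = np.asarray(resolution_nm, dtype=float)
    half_nm = half_width_um * 1000.0
    shape = tuple(int(np.ceil(2.0 * half_nm / r)) for r in res)
    center = np.array([s * r / 2.0 for s, r in zip(shape, res)])

    soma_mask = _sphere_mask(shape, center, soma_radius_um * 1000.0, res)
    nucleus_mask = _sphere_mask(shape, center, nucleus_spec.radius_um * 1000.0, res)

    cell = np.full(shape, background_label, dtype=np.int32)
    cell[soma_mask] = soma_label

    rng = split_rng(seed, 1)
    if gap_slab is not None:
        k0, thick = gap_slab
        cell[:, :, k0:k0 + thick][soma_mask[:, :, k0:k0 + thick]] = background_label
    if fragment is not None:
        (ox, oy, oz), n_frag = fragment
        ci = np.round(center / res).astype(int)
        for t in range(n_frag):
            idx = (ci[0] + ox + t, ci[1] + oy, ci[2] + oz)
            if all(0 <= idx[d] < shape[d] for d in range(3)):
                cell[idx] = soma_label

    # error voids inside the (clipped) 15-um bounding box, background only
    bbox_half = min(15_000.0, half_nm)
    lo = np.maximum(np.floor((center - bbox_half) / res), 0).astype(int)
    hi = np.minimum(np.ceil((center + bbox_half) / res), shape).astype(int)
    if error_void_fraction > 0:
        box = cell[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        n_box = box.size
        n_target = int(round(error_void_fraction * n_box))
        bg = np.flatnonzero(box == background_label)
        if len(bg) < n_target:
            raise ValueError("not enough background voxels for the requested "
                             "error_void_fraction")
        chosen = rng.choice(bg, size=n_target, replace=False)
        ii, jj, kk = np.unravel_index(chosen, box.shape)
        cell[ii + lo[0], jj + lo[1], kk + lo[2]] = 0

    nucleus = np.zeros(shape, dtype=np.int32)
    nucleus[nucleus_mask] = nucleus_label

    # synapses on the soma surface
    if n_soma_synapses > 0:
        dirs = rng.normal(size=(n_soma_synapses, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = center[None, :] + dirs * soma_radius_um * 1000.0
        synapses = pd.DataFrame({
            "pre_id": 10_000 + np.arange(n_soma_synapses),
            "post_id": soma_label,
            "x_nm": pos[:, 0], "y_nm": pos[:, 1], "z_nm": pos[:, 2],
            "size_vx": rng.integers(100, 2000, size=n_soma_synapses),
        })
    else:
        synapses = empty_synapse_table()

    vol_kwargs = dict(resolution_nm=tuple(res), offset_nm=(0.0, 0.0, 0.0))
    return (LabeledVolume(cell, **vol_kwargs),
            LabeledVolume(nucleus, **vol_kwargs),
            synapses)


# ---------------------------------------------------------------------------
# postsynaptic-shape phantoms


def _capsule(radius: float, length: float, axis: int,
             max_edge: float | None = None) -> trimesh.Trimesh:
    cap = trimesh.creation.capsule(height=length, radius=radius, count=(24, 24))
    # the lateral wall is a single band of long triangles; subdivide so the
    # surface has vertices everywhere (region cutouts select by vertex)
    if max_edge is None:
        max_edge = radius * 0.8
    verts, faces = trimesh.remesh.subdivide_to_size(
        cap.vertices, cap.faces, max_edge=max_edge, max_iter=6)
    cap = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if axis == 0:
        rot = trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])
        cap.apply_transform(rot)
    elif axis == 1:
        rot = trimesh.transformations.rotation_matrix(-np.pi / 2, [1, 0, 0])
        cap.apply_transform(rot)
    return cap


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(points - (a + t[:, None] * ab), axis=1)


def _spine_phantom(scale: float) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Head-on-stalk attached to a dendritic shaft; synapse on the head.

    Built as one connected watertight surface by voxelizing the implicit
    union of shaft capsule, thin neck and spherical head (20-nm grid) and
    running marching cubes, mirroring how real somatic surfaces arise from
    segmentation masks.
    """
    from skimage import measure as _measure
    from trimesh import smoothing as _smoothing

    vx = 25.0 * scale
    lo = np.array([-1800.0, -480.0, -480.0]) * scale
    hi = np.array([1800.0, 1620.0, 480.0]) * scale
    shape = np.ceil((hi - lo) / vx).astype(int)
    grid = np.stack(np.meshgrid(
        lo[0] + (np.arange(shape[0]) + 0.5) * vx,
        lo[1] + (np.arange(shape[1]) + 0.5) * vx,
        lo[2] + (np.arange(shape[2]) + 0.5) * vx,
        indexing="ij"), axis=-1).reshape(-1, 3)
    s = scale
    shaft = _segment_distance(grid, np.array([-1500.0, 0, 0]) * s,
                              np.array([1500.0, 0, 0]) * s) <= 300 * s
    neck = _segment_distance(grid, np.array([0.0, 0, 0]),
                             np.array([0.0, 1030.0, 0]) * s) <= 75 * s
    head = np.linalg.norm(grid - np.array([0.0, 1180.0, 0.0]) * s, axis=1) <= 250 * s
    mask = (shaft | neck | head).reshape(shape)
    verts, faces, _, _ = _measure.marching_cubes(
        np.pad(mask, 1).astype(np.float32), level=0.5, spacing=(vx, vx, vx))
    verts = verts + lo - vx * 0.5
    mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=True)
    # remove the voxel staircase so local thickness is well defined
    _smoothing.filter_taubin(mesh, lamb=0.5, nu=-0.53, iterations=10)
    synapse = np.array([0.0, 1430.0 * s, 0.0])
    return mesh, synapse


def _shaft_phantom(scale: float) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Uniform dendritic shaft; synapse on its side."""
    shaft = _capsule(radius=250 * scale, length=3000 * scale, axis=0)
    synapse = np.array([0.0, 250 * scale, 0.0])
    return shaft, synapse


def _soma_patch_phantom(scale: float) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Large-radius spherical cap; synapse at the apex."""
    big_radius = 6000 * scale
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=big_radius)
    apex = np.array([big_radius, 0.0, 0.0])
    d = np.linalg.norm(sphere.vertices - apex, axis=1)
    keep_vert = d <= 3200 * scale
    keep_face = keep_vert[sphere.faces].all(axis=1)
    patch = trimesh.Trimesh(
        vertices=sphere.vertices, faces=sphere.faces[keep_face], process=False)
    patch.remove_unreferenced_vertices()
    return patch, apex


PSS_CLASSES = ("spine", "shaft", "soma_patch")

_PSS_BUILDERS = {
    "spine": _spine_phantom,
    "shaft": _shaft_phantom,
    "soma_patch": _soma_patch_phantom,
}


def make_pss_phantoms(class_mix: dict[str, int], seed: int = 0,
                      ) -> list[tuple[trimesh.Trimesh, str, np.ndarray]]:
    """Phantom postsynaptic shapes (each fits a 3,500-nm cutout).

    Instances of a class vary by a +-12% isotropic scale jitter so that a
    corpus has some shape diversity for embedding/dictionary training.
    """
    unknown = set(class_mix) - set(PSS_CLASSES)
    if unknown:
        raise ValueError(f"unknown PSS classes: {sorted(unknown)}")
    if any(n < 0 for n in class_mix.values()):
        raise ValueError("counts must be non-negative")
    out: list[tuple[trimesh.Trimesh, str, np.ndarray]] = []
    for ci, cls in enumerate(PSS_CLASSES):
        n = int(class_mix.get(cls, 0))
        rng = split_rng(seed, 2, ci)
        for _ in range(n):
            scale = 1.0 + rng.uniform(-0.12, 0.12)
            mesh, synapse = _PSS_BUILDERS[cls](scale)
            out.append((mesh, cls, synapse))
    return out


# ---------------------------------------------------------------------------
# cohorts with planted class structure and planted axons


@dataclass
class CohortSpec:
    """Cohort of cells with class-conditional Gaussian features and planted
    connectivity-defined axons."""

    n_cells: int
    class_proportions: dict[str, float]
    feature_model: dict[str, tuple[np.ndarray, np.ndarray]]
    planted_axons: list[tuple] = field(default_factory=list)
    seed: int = 0
    #: fraction of a planted chandelier axon's outputs placed in the AIS window
    ais_fraction: float = 0.8
    #: fraction of a planted NP-targeting axon's outputs onto 5P-NP cells
    np_fraction: float = 0.5
    n_outputs_per_axon: int = 150

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        total = sum(self.class_proportions.values())
        if self.class_proportions and abs(total - 1.0) > 1e-6:
            raise ValueError("class proportions must sum to 1")
        for label, (mean, cov) in self.feature_model.items():
            cov = np.asarray(cov, dtype=float)
            mean = np.asarray(mean, dtype=float)
            if cov.shape != (len(mean), len(mean)):
                raise ValueError(f"covariance shape mismatch for class {label!r}")
            eig = np.linalg.eigvalsh(cov)
            if eig.min() < -1e-9 * max(1.0, eig.max()):
                raise ValueError(f"degenerate (non-PSD) covariance for class {label!r}")


@dataclass
class Cohort:
    features: pd.DataFrame
    labels: pd.Series
    synapses: pd.DataFrame
    soma_positions: pd.DataFrame
    truth: dict

    def __iter__(self):
        return iter((self.features, self.labels, self.synapses, self.soma_positions))


def default_feature_model(
    classes: list[str],
    n_features: int = 13,
    separation_sd: float = 8.0,
    seed: int = 0,
    base_dims: int = 13,
    pss_informative_classes: tuple = ("BC", "BPC", "MC", "NGC"),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Unit-covariance Gaussians with class means on random unit directions
    scaled by ``separation_sd``.

    Random directions in >= 13 dimensions are near-orthogonal, so pairwise
    class separation is ~ sqrt(2) x separation_sd.  When ``n_features``
    exceeds ``base_dims`` (i.e. a PSS block is present), class means are
    placed in the first ``base_dims`` nucleus/soma dimensions — the block
    models 1-4 consume — and classes named in ``pss_informative_classes``
    (the inhibitory subclasses) receive an additional mean component in the
    PSS block, emulating the extra subtype information carried by
    postsynaptic shapes.
    """
    rng = split_rng(seed, 3)
    base_dims = min(base_dims, n_features)
    pss_dims = n_features - base_dims
    model = {}
    for cls in classes:
        mean = np.zeros(n_features)
        d = rng.normal(size=base_dims)
        mean[:base_dims] = separation_sd * d / np.linalg.norm(d)
        if pss_dims and cls in pss_informative_classes:
            dp = rng.normal(size=pss_dims)
            mean[base_dims:] = separation_sd * dp / np.linalg.norm(dp)
        model[cls] = (mean, np.eye(n_features))
    return model


def _angle_to_direction(phi_deg: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Unit vectors at angle phi from the pia direction (-y), azimuth psi."""
    phi = np.radians(phi_deg)
    return np.column_stack([
        np.sin(phi) * np.cos(psi),
        -np.cos(phi),           # phi = 0 -> -y (toward pia, 'directly above')
        np.sin(phi) * np.sin(psi),
    ])


def make_cohort(spec: CohortSpec, feature_names: list[str] | None = None) -> Cohort:
    """Draw a cohort: features, labels, soma positions and planted-axon
    synapse tables, with generator bookkeeping in ``truth``."""
    spec.validate()
    classes = sorted(spec.class_proportions)
    n_feat = (len(next(iter(spec.feature_model.values()))[0])
              if spec.feature_model else 0)
    if feature_names is None:
        feature_names = [f"f{i:03d}" for i in range(n_feat)]

    if spec.n_cells == 0:
        features = pd.DataFrame(columns=feature_names, dtype=float)
        features.index.name = "cell_id"
        return Cohort(features, pd.Series(dtype=object, name="label"),
                      empty_synapse_table(),
                      pd.DataFrame(columns=["x_nm", "y_nm", "z_nm"]),
                      {"axons": pd.DataFrame()})

    rng_labels = split_rng(spec.seed, 4)
    probs = np.array([spec.class_proportions[c] for c in classes])
    labels = rng_labels.choice(classes, size=spec.n_cells, p=probs)

    rng_feat = split_rng(spec.seed, 5)
    X = np.zeros((spec.n_cells, n_feat))
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) == 0:
            continue
        mean, cov = spec.feature_model[cls]
        X[idx] = rng_feat.multivariate_normal(
            np.asarray(mean, dtype=float), np.asarray(cov, dtype=float),
            size=len(idx), method="svd")

    cell_ids = np.arange(1, spec.n_cells + 1)
    features = pd.DataFrame(X, index=pd.Index(cell_ids, name="cell_id"),
                            columns=feature_names)
    labels = pd.Series(labels, index=features.index, name="label")

    rng_pos = split_rng(spec.seed, 6)
    pos = np.column_stack([
        rng_pos.uniform(0, 400_000, spec.n_cells),      # x
        rng_pos.uniform(50_000, 800_000, spec.n_cells), # y = depth axis
        rng_pos.uniform(0, 400_000, spec.n_cells),      # z
    ])
    soma_positions = pd.DataFrame(pos, index=features.index,
                                  columns=["x_nm", "y_nm", "z_nm"])

    syn_frames: list[pd.DataFrame] = []
    axon_rows: list[dict] = []
    next_axon = 100_000
    for ai, motif_spec in enumerate(spec.planted_axons):
        motif, count = motif_spec[0], int(motif_spec[1])
        for _ in range(count):
            axon_id = next_axon
            next_axon += 1
            rng_ax = split_rng(spec.seed, 7, axon_id)
            frame, row = _plant_axon(motif, axon_id, spec, labels,
                                     soma_positions, rng_ax)
            syn_frames.append(frame)
            axon_rows.append(row)
    synapses = (pd.concat(syn_frames, ignore_index=True) if syn_frames
                else empty_synapse_table())
    truth = {"axons": pd.DataFrame(axon_rows)}
    return Cohort(features, labels, synapses, soma_positions, truth)


def _plant_axon(motif: str, axon_id: int, spec: CohortSpec,
                labels: pd.Series, soma_positions: pd.DataFrame,
                rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    n_out = spec.n_outputs_per_axon
    cell_ids = labels.index.to_numpy()
    pos = soma_positions.to_numpy()

    if motif == "chandelier":
        n_ais = int(round(spec.ais_fraction * n_out))
        is_ais = np.zeros(n_out, dtype=bool)
        is_ais[:n_ais] = True
        targets = rng.choice(len(cell_ids), size=n_out)
        phi = np.where(is_ais, rng.uniform(161, 179, n_out), rng.uniform(5, 150, n_out))
        r_um = rng.uniform(5, 55, n_out)
        true_fraction = n_ais / n_out
    elif motif == "np_targeting":
        np_ids = np.flatnonzero(labels.to_numpy() == "5P-NP")
        other = np.flatnonzero(labels.to_numpy() != "5P-NP")
        if len(np_ids) == 0:
            raise ValueError("np_targeting motif requires 5P-NP cells in the cohort")
        n_np = int(round(spec.np_fraction * n_out))
        targets = np.concatenate([rng.choice(np_ids, size=n_np),
                                  rng.choice(other if len(other) else np_ids,
                                             size=n_out - n_np)])
        phi = rng.uniform(5, 175, n_out)
        r_um = rng.uniform(5, 55, n_out)
        true_fraction = n_np / n_out
    elif motif == "random":
        targets = rng.choice(len(cell_ids), size=n_out)
        phi = rng.uniform(1, 179, n_out)
        r_um = rng.uniform(5, 55, n_out)
        true_fraction = np.nan
    else:
        raise ValueError(f"unknown connectivity motif: {motif!r}")

    psi = rng.uniform(0, 2 * np.pi, n_out)
    direction = _angle_to_direction(phi, psi)
    syn = pos[targets] + direction * (r_um[:, None] * 1000.0)
    frame = pd.DataFrame({
        "pre_id": axon_id,
        "post_id": cell_ids[targets],
        "x_nm": syn[:, 0], "y_nm": syn[:, 1], "z_nm": syn[:, 2],
        "size_vx": rng.integers(100, 2000, n_out),
    })
    row = {"axon_id": axon_id, "motif": motif, "planted_fraction": true_fraction}
    return frame, row
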