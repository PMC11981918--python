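"""Shared fixtures: phantom meshes, volumes, extracted PSS pools and a
trained cascade.  Expensive fixtures are session-scoped and sized for a
single CPU."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from perisoma.synthetic import (CohortSpec, NucleusPhantomSpec, default_feature_model,
                                make_cell_volume, make_cohort, make_nucleus_phantom,
                                make_pss_phantoms, pss_column_names,
                                NUCLEUS_FEATURE_NAMES, SOMA_FEATURE_NAMES)
from perisoma.pss import (DeterministicShapeEncoder, extract_pss, normalize_pose,
                          segment_by_thickness, synapse_region_mesh)
from perisoma.classify import Taxonomy, train_cascade

ALL_FEATURE_NAMES = (list(NUCLEUS_FEATURE_NAMES) + list(SOMA_FEATURE_NAMES)
                     + pss_column_names())


@pytest.fixture(scope="session")
def sphere_phantom():
    return make_nucleus_phantom(NucleusPhantomSpec(
        radius_um=5.0, n_folds=0, mesh_resolution_nm=250, seed=0))


@pytest.fixture(scope="session")
def folded_phantom():
    spec = NucleusPhantomSpec(radius_um=5.0, n_folds=4, fold_depth_nm=1500.0,
                              fold_area_fraction=0.2, mesh_resolution_nm=200, seed=2)
    mesh, true_fraction = make_nucleus_phantom(spec)
    return spec, mesh, true_fraction


@pytest.fixture(scope="session")
def coarse_cell_volume():
    """Nucleus-in-soma phantom at a coarse resolution for fast voxel tests."""
    spec = NucleusPhantomSpec(radius_um=4.0, n_folds=0, seed=0)
    return make_cell_volume(spec, soma_radius_um=8.0, n_soma_synapses=12,
                            error_void_fraction=0.0,
                            resolution_nm=(128.0, 128.0, 80.0),
                            half_width_um=10.0, seed=5)


@pytest.fixture(scope="session")
def spine_extractions():
    """100 spine phantoms pushed through region cutout, thickness
    segmentation and PSS extraction (shared by several suites)."""
    phantoms = make_pss_phantoms({"spine": 100}, seed=11)
    results = []
    for mesh, cls, syn in phantoms:
        region = synapse_region_mesh(mesh, syn)
        segments = segment_by_thickness(region)
        pss = extract_pss(region, segments, syn)
        results.append((mesh, syn, pss))
    return results


@pytest.fixture(scope="session")
def pss_pool_latents(spine_extractions):
    """Latents of extracted phantom PSS of the three classes, from the
    deterministic encoder."""
    encoder = DeterministicShapeEncoder()
    latents, labels = [], []
    for mesh, syn, pss in spine_extractions[:30]:
        latents.append(encoder.encode(normalize_pose(pss.mesh, 256, seed=0)))
        labels.append("spine")
    for cls, n in (("shaft", 25), ("soma_patch", 10)):
        for mesh, _, syn in make_pss_phantoms({cls: n}, seed=12):
            region = synapse_region_mesh(mesh, syn)
            segments = segment_by_thickness(region)
            pss = extract_pss(region, segments, syn)
            latents.append(encoder.encode(normalize_pose(pss.mesh, 256, seed=0)))
            labels.append(cls)
    return np.array(latents), np.array(labels)


def voxel_union_mesh(masks_fn, lo, hi, vx=25.0):
    """Marching-cubes mesh of an implicit union, Taubin-smoothed (helper for
    custom phantoms such as dumbbells)."""
    import trimesh
    from skimage import measure as sk_measure

    shape = np.ceil((np.asarray(hi) - lo) / vx).astype(int)
    grid = np.stack(np.meshgrid(
        *[lo[d] + (np.arange(shape[d]) + 0.5) * vx for d in range(3)],
        indexing="ij"), axis=-1).reshape(-1, 3)
    mask = masks_fn(grid).reshape(shape)
    verts, faces, _, _ = sk_measure.marching_cubes(
        np.pad(mask, 1).astype(np.float32), 0.5, spacing=(vx, vx, vx))
    mesh = trimesh.Trimesh(vertices=verts + np.asarray(lo) - vx / 2,
                           faces=faces[:, ::-1], process=True)
    trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=-0.53, iterations=10)
    return mesh


@pytest.fixture(scope="session")
def dumbbell_mesh():
    """Two bulbs (radius 400 nm) joined by a neck of 1/4 their thickness."""
    def masks(g):
        b1 = np.linalg.norm(g - [-900.0, 0, 0], axis=1) <= 400
        b2 = np.linalg.norm(g - [900.0, 0, 0], axis=1) <= 400
        neck = (np.abs(g[:, 0]) <= 900) & (np.hypot(g[:, 1], g[:, 2]) <= 100)
        return b1 | b2 | neck
    return voxel_union_mesh(masks, [-1400, -500, -500], [1400, 500, 500])


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated 17-class cohort (13 nucleus/soma + 120 PSS features)."""
    taxonomy = Taxonomy()
    classes = list(taxonomy.leaves)
    model = default_feature_model(classes, n_features=133, separation_sd=6, seed=0)
    spec = CohortSpec(
        n_cells=600,
        class_proportions={c: 1.0 / len(classes) for c in classes},
        feature_model=model,
        planted_axons=[("chandelier", 2), ("np_targeting", 2), ("random", 2)],
        seed=3)
    return make_cohort(spec, feature_names=ALL_FEATURE_NAMES)


@pytest.fixture(scope="session")
def trained_cascade(separated_cohort):
    return train_cascade(separated_cohort.features, separated_cohort.labels,
                         n_draws=5, cv_folds=3, seed=0)
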