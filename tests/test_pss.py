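import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from skimage import measure as sk_measure

from perisoma.pss import (DeterministicShapeEncoder, PSSDescriptor,
                          ShapeDictionary, build_dictionary, extract_pss,
                          normalize_pose, segment_by_thickness,
                          spatial_histogram, synapse_region_mesh,
                          train_autoencoder)
from perisoma.synthetic import make_pss_phantoms, split_rng


@pytest.fixture(scope="module")
def dumbbell(dumbbell_mesh):
    return dumbbell_mesh


class TestRegionMesh:
    def test_cutout_spans_at_most_twice_the_radius(self):
        (mesh, _, _), = make_pss_phantoms({"shaft": 1}, seed=1)
        synapse = np.array([0.0, 250.0, 0.0])
        region = synapse_region_mesh(mesh, synapse, radius_nm=1500.0)
        span = region.vertices[:, 0].max() - region.vertices[:, 0].min()
        assert span <= 2 * 1500.0 + 300.0   # + one face size of slack

    def test_radius_larger_than_phantom_returns_whole_component(self):
        (mesh, _, syn), = make_pss_phantoms({"soma_patch": 1}, seed=1)
        region = synapse_region_mesh(mesh, syn, radius_nm=50_000.0)
        assert len(region.faces) == len(mesh.faces)

    def test_only_synapse_bearing_branch_returned(self):
        # two parallel shafts within the cutout radius but not connected
        a = trimesh.creation.capsule(height=3000.0, radius=200.0)
        b = a.copy()
        b.apply_translation([1200.0, 0.0, 0.0])
        both = trimesh.util.concatenate([a, b])
        synapse = np.array([200.0, 0.0, 0.0])    # on shaft a
        region = synapse_region_mesh(both, synapse)
        assert region.vertices[:, 0].max() < 600.0

    def test_no_face_in_radius_raises(self):
        (mesh, _, _), = make_pss_phantoms({"shaft": 1}, seed=1)
        with pytest.raises(ValueError):
            synapse_region_mesh(mesh, [50_000.0, 0, 0], radius_nm=100.0)


class TestThicknessSegmentation:
    def test_uniform_cylinder_is_one_segment(self):
        (mesh, _, _), = make_pss_phantoms({"shaft": 1}, seed=2)
        segments = segment_by_thickness(mesh)
        assert len(segments) == 1

    def test_dumbbell_neck_separated_from_bulbs(self, dumbbell):
        segments = segment_by_thickness(dumbbell)
        assert len(segments) >= 2
        thicknesses = sorted(s.thickness_nm for s in segments)
        # thinnest segment is the neck (~200 nm), thickest a bulb (~800 nm)
        assert thicknesses[0] < 350.0
        assert thicknesses[-1] > 600.0
        thinnest = min(segments, key=lambda s: s.thickness_nm)
        assert np.abs(thinnest.mesh.vertices[:, 0]).max() < 700.0

    def test_spine_head_and_stalk_not_in_shaft_segment(self, spine_extractions):
        mesh, syn, _ = spine_extractions[0]
        region = synapse_region_mesh(mesh, syn)
        segments = segment_by_thickness(region)
        by_thickness = sorted(segments, key=lambda s: s.thickness_nm)
        neck = by_thickness[0]
        shaft = max(segments, key=lambda s: s.thickness_nm)
        # the neck (thinnest) contains no far-shaft faces; the shaft does
        assert np.abs(neck.mesh.vertices[:, 0]).max() < 600.0
        assert np.abs(shaft.mesh.vertices[:, 0]).max() > 1200.0


class TestExtractPSS:
    def test_spine_pss_has_head_but_not_far_shaft(self, spine_extractions):
        correct = 0
        for mesh, syn, pss in spine_extractions:
            ymax = mesh.vertices[:, 1].max()
            has_head = pss.mesh.vertices[:, 1].max() > 0.85 * ymax
            no_shaft = np.abs(pss.mesh.vertices[:, 0]).max() < 700.0
            correct += has_head and no_shaft
        assert correct >= 0.9 * len(spine_extractions)

    def test_shaft_synapse_stays_on_shaft(self):
        (mesh, _, syn), = make_pss_phantoms({"shaft": 1}, seed=3)
        region = synapse_region_mesh(mesh, syn)
        pss = extract_pss(region, segment_by_thickness(region), syn)
        assert pss.on_shaft
        assert not pss.fallback

    def test_soma_patch_pss_is_larger_than_spine_pss(self, spine_extractions):
        (mesh, _, syn), = make_pss_phantoms({"soma_patch": 1}, seed=3)
        region = synapse_region_mesh(mesh, syn)
        patch = extract_pss(region, segment_by_thickness(region), syn)
        spine_areas = [pss.mesh.area for _, _, pss in spine_extractions[:20]]
        assert patch.mesh.area > max(spine_areas)


class TestNormalizePose:
    def test_output_size_and_centering(self):
        (mesh, _, _), = make_pss_phantoms({"shaft": 1}, seed=4)
        cloud = normalize_pose(mesh, n_points=333, seed=0)
        assert cloud.shape == (333, 3)
        np.testing.assert_allclose(cloud.mean(axis=0), 0.0, atol=1e-9)

    def test_rotation_invariance(self):
        (mesh, _, _), = make_pss_phantoms({"spine": 1}, seed=4)
        c1 = normalize_pose(mesh, 256, seed=0)
        rotated = mesh.copy()
        rotated.apply_transform(trimesh.transformations.rotation_matrix(
            2.1, [3, 1, -2], point=[100, 50, -20]))
        c2 = normalize_pose(rotated, 256, seed=0)
        np.testing.assert_allclose(c1, c2, atol=1e-6)

    def test_mirror_symmetric_shape_stable_under_resampling(self):
        (mesh, _, _), = make_pss_phantoms({"shaft": 1}, seed=5)
        # distributional descriptor: per-axis absolute moments
        stats = []
        for seed in (0, 1, 2):
            c = normalize_pose(mesh, 2000, seed=seed)
            stats.append(np.abs(c).mean(axis=0))
        spread = np.ptp(np.array(stats), axis=0) / np.mean(stats, axis=0)
        assert spread.max() < 0.05

    def test_degenerate_mesh_raises(self):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            normalize_pose(empty, 100)


@pytest.fixture(scope="module")
def phantom_corpus():
    phantoms = make_pss_phantoms({"spine": 40, "shaft": 40, "soma_patch": 40},
                                 seed=7)
    clouds = [normalize_pose(m, 128, seed=0) for m, _, _ in phantoms]
    labels = [c for _, c, _ in phantoms]
    return clouds, labels


class TestAutoencoder:
    def test_latent_size_and_determinism(self, phantom_corpus):
        clouds, _ = phantom_corpus
        ae = train_autoencoder(clouds[:20], latent_size=1024, epochs=10, seed=3)
        z = ae.encode(clouds[0])
        assert z.shape == (1024,)
        np.testing.assert_array_equal(z, ae.encode(clouds[0].copy()))
        ae2 = train_autoencoder(clouds[:20], latent_size=1024, epochs=10, seed=3)
        np.testing.assert_array_equal(z, ae2.encode(clouds[0]))

    def test_reconstruction_loss_decreases(self, phantom_corpus):
        clouds, _ = phantom_corpus
        ae = train_autoencoder(clouds, latent_size=256, epochs=40, seed=0)
        assert ae.loss_history_[-1] < ae.loss_history_[0]

    def test_latents_linearly_separable_by_class(self, phantom_corpus):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score
        clouds, labels = phantom_corpus
        ae = train_autoencoder(clouds, latent_size=1024, epochs=60, seed=0)
        latents = ae.encode_many(clouds)
        score = cross_val_score(LogisticRegression(max_iter=3000),
                                latents, labels, cv=5).mean()
        assert score >= 0.90

    def test_invalid_latent_size(self):
        with pytest.raises(ValueError):
            train_autoencoder([np.zeros((4, 3))] * 3, latent_size=0)


class TestDictionary:
    def test_k_distinct_points_recovered_exactly(self):
        rng = split_rng(0, 9)
        centres = rng.normal(size=(5, 8)) * 10
        latents = np.repeat(centres, 20, axis=0)
        d = build_dictionary(latents, k=5, seed=0)
        got = d.centres[np.lexsort(d.centres.T)]
        want = centres[np.lexsort(centres.T)]
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_default_dictionary_has_thirty_centres(self, pss_pool_latents):
        latents, _ = pss_pool_latents
        d = build_dictionary(latents, seed=0)
        assert d.k == 30

    def test_fixed_seed_reproducible(self, pss_pool_latents):
        latents, _ = pss_pool_latents
        d1 = build_dictionary(latents, k=10, seed=4)
        d2 = build_dictionary(latents, k=10, seed=4)
        np.testing.assert_array_equal(d1.centres, d2.centres)

    def test_too_few_distinct_latents(self):
        with pytest.raises(ValueError):
            build_dictionary(np.ones((100, 16)), k=30)


def _descriptor(cluster, distance):
    return PSSDescriptor(synapse_id=0, mesh=None, latent=np.zeros(4),
                         cluster=cluster, distance_to_nucleus_um=distance)


def _toy_dictionary(k=30):
    centres = np.zeros((k, 4))
    centres[:, 0] = np.arange(k)
    return ShapeDictionary(centres=centres, ordering=np.arange(k))


class TestSpatialHistogram:
    def test_empty_list_gives_zero_matrix(self):
        hist = spatial_histogram([], _toy_dictionary())
        assert hist.counts.shape == (30, 4)
        assert hist.counts.sum() == 0
        assert hist.flattened.shape == (120,)

    def test_counts_are_conserved(self):
        rng = split_rng(0, 10)
        descriptors = [_descriptor(int(rng.integers(0, 30)),
                                   float(rng.uniform(0, 60)))
                       for _ in range(137)]
        hist = spatial_histogram(descriptors, _toy_dictionary())
        assert hist.counts.sum() == 137

    def test_mass_lands_in_the_right_cell(self):
        descriptors = [_descriptor(3, 5.0)] * 7
        hist = spatial_histogram(descriptors, _toy_dictionary())
        assert hist.counts[3, 0] == 7
        assert hist.counts.sum() == 7

    def test_bin_edges_half_open_last_closed(self):
        hist = spatial_histogram(
            [_descriptor(0, 15.0), _descriptor(0, 60.0)], _toy_dictionary())
        assert hist.counts[0, 1] == 1     # 15.0 falls into [15, 30)
        assert hist.counts[0, 3] == 1     # 60.0 falls into the closed last bin

    def test_distance_beyond_range_raises(self):
        with pytest.raises(ValueError):
            spatial_histogram([_descriptor(0, 61.0)], _toy_dictionary())

    @given(st.lists(st.tuples(st.integers(0, 29),
                              st.floats(0.0, 60.0)), max_size=60))
    @settings(deadline=None, max_examples=25)
    def test_row_and_column_sums_partition_total(self, pairs):
        descriptors = [_descriptor(c, d) for c, d in pairs]
        hist = spatial_histogram(descriptors, _toy_dictionary())
        assert hist.counts.sum(axis=0).sum() == len(pairs)
        assert hist.counts.sum(axis=1).sum() == len(pairs)


def test_spiny_and_smooth_cells_have_distinct_shape_marginals(pss_pool_latents):
    """Phantom cells whose proximal synapses land on spines versus shafts
    produce spatial shape histograms whose shape-marginals differ."""
    from scipy.stats import mannwhitneyu

    latents, labels = pss_pool_latents
    dictionary = build_dictionary(latents, k=10, seed=0)
    clusters = dictionary.assign(latents)
    spine_pool = clusters[labels == "spine"]
    shaft_pool = clusters[labels == "shaft"]
    spine_clusters = set(np.unique(spine_pool))

    rng = split_rng(0, 11)

    def cell_histogram(spiny: bool):
        n_syn = 30
        p_spine = 0.8 if spiny else 0.1
        descriptors = []
        for _ in range(n_syn):
            pool = spine_pool if rng.random() < p_spine else shaft_pool
            descriptors.append(_descriptor(int(rng.choice(pool)),
                                           float(rng.uniform(0, 60))))
        dummy = _toy_dictionary(10)
        return spatial_histogram(descriptors, dummy).counts

    def spine_mass(counts):
        return sum(counts[c].sum() for c in spine_clusters)

    spiny = [spine_mass(cell_histogram(True)) for _ in range(20)]
    smooth = [spine_mass(cell_histogram(False)) for _ in range(20)]
    p = mannwhitneyu(spiny, smooth).pvalue
    assert p < 0.01
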