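import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perisoma.connectivity import (TargetingProfile, chandelier_score,
                                   fisher_enrichment, nearest_neighbors,
                                   proofreading_deltas, radial_extent,
                                   subclass_density_map, target_fractions,
                                   targeting_profile, truncation_estimate)
from perisoma.synthetic import split_rng
from perisoma.types import DepthReference

from _oracles import fisher_two_tailed_enumeration


class TestNearestNeighbors:
    def test_two_points(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]],
                          index=pd.Index([10, 20], name="cell_id"))
        assert nearest_neighbors(df, 10, k=1) == [20]

    def test_duplicate_of_query_is_rank_one(self):
        df = pd.DataFrame([[0.0], [0.0], [5.0]],
                          index=pd.Index([1, 2, 3], name="cell_id"))
        assert nearest_neighbors(df, 1, k=2) == [2, 3]

    def test_matches_brute_force_on_random_matrix(self):
        rng = split_rng(0, 30)
        X = rng.normal(size=(100, 7))
        ids = pd.Index(rng.permutation(np.arange(1000, 1100)), name="cell_id")
        df = pd.DataFrame(X, index=ids)
        query = ids[17]
        got = nearest_neighbors(df, query, k=20)
        d = np.linalg.norm(X - X[17], axis=1)
        order = np.lexsort((ids.to_numpy(), d))
        want = [ids[i] for i in order if ids[i] != query][:20]
        assert got == want

    def test_k_too_large_raises(self):
        df = pd.DataFrame(np.zeros((5, 2)),
                          index=pd.Index(range(5), name="cell_id"))
        with pytest.raises(ValueError):
            nearest_neighbors(df, 0, k=5)


def _profile_from_offsets(offsets_nm, soma=np.zeros(3)):
    n = len(offsets_nm)
    outputs = pd.DataFrame({
        "pre_id": 1, "post_id": 7,
        "x_nm": [soma[0] + o[0] for o in offsets_nm],
        "y_nm": [soma[1] + o[1] for o in offsets_nm],
        "z_nm": [soma[2] + o[2] for o in offsets_nm],
        "size_vx": 100,
    })
    somata = pd.DataFrame([[soma[0], soma[1], soma[2]]],
                          columns=["x_nm", "y_nm", "z_nm"],
                          index=pd.Index([7], name="cell_id"))
    with pytest.warns(UserWarning):   # small axon, below 100 outputs
        return targeting_profile(outputs, somata, DepthReference())


class TestTargetingGeometry:
    def test_pure_depth_displacement_is_180(self):
        profile = _profile_from_offsets([(0.0, 30_000.0, 0.0)])
        assert profile.records["phi_deg"].iloc[0] == pytest.approx(180.0)
        assert profile.records["r_um"].iloc[0] == pytest.approx(30.0)

    def test_pure_pia_displacement_is_0(self):
        profile = _profile_from_offsets([(0.0, -10_000.0, 0.0)])
        assert profile.records["phi_deg"].iloc[0] == pytest.approx(0.0)

    def test_perpendicular_displacement_is_90(self):
        profile = _profile_from_offsets([(5_000.0, 0.0, 0.0)])
        assert profile.records["phi_deg"].iloc[0] == pytest.approx(90.0)

    def test_unknown_target_excluded_and_counted(self):
        outputs = pd.DataFrame({
            "pre_id": [1, 1], "post_id": [7, 99],
            "x_nm": [0.0, 0.0], "y_nm": [1000.0, 1000.0],
            "z_nm": [0.0, 0.0], "size_vx": [10, 10]})
        somata = pd.DataFrame([[0.0, 0.0, 0.0]],
                              columns=["x_nm", "y_nm", "z_nm"],
                              index=pd.Index([7], name="cell_id"))
        with pytest.warns(UserWarning):
            profile = targeting_profile(outputs, somata)
        assert len(profile.records) == 1
        assert profile.n_unmatched == 1


class TestChandelierScore:
    def test_all_ais_synapses(self):
        profile = TargetingProfile(
            records=pd.DataFrame({"phi_deg": [170.0] * 10, "r_um": [20.0] * 10,
                                  "target_id": range(10)}),
            n_outputs=10)
        fraction, is_chandelier = chandelier_score(profile)
        assert fraction == 1.0 and is_chandelier

    def test_exactly_forty_percent_is_not_chandelier(self):
        phi = [170.0] * 4 + [90.0] * 6
        profile = TargetingProfile(
            records=pd.DataFrame({"phi_deg": phi, "r_um": [20.0] * 10,
                                  "target_id": range(10)}),
            n_outputs=10)
        fraction, is_chandelier = chandelier_score(profile)
        assert fraction == pytest.approx(0.40)
        assert not is_chandelier       # strict >

    def test_far_ais_angle_synapses_do_not_count(self):
        profile = TargetingProfile(
            records=pd.DataFrame({"phi_deg": [170.0] * 10,
                                  "r_um": [80.0] * 10,
                                  "target_id": range(10)}),
            n_outputs=10)
        fraction, _ = chandelier_score(profile)
        assert fraction == 0.0

    def test_planted_chandelier_recovers_planted_fraction(self, separated_cohort):
        axons = separated_cohort.truth["axons"]
        row = axons[axons["motif"] == "chandelier"].iloc[0]
        outputs = separated_cohort.synapses[
            separated_cohort.synapses["pre_id"] == row["axon_id"]]
        profile = targeting_profile(outputs, separated_cohort.soma_positions,
                                    target_labels=separated_cohort.labels)
        fraction, is_chandelier = chandelier_score(profile)
        n = profile.n_outputs
        binom_3se = 3 * np.sqrt(0.8 * 0.2 / n)
        assert abs(fraction - row["planted_fraction"]) <= binom_3se + 1.0 / n
        assert is_chandelier


class TestTargetFractions:
    def _profile(self, labels):
        return TargetingProfile(
            records=pd.DataFrame({
                "phi_deg": 90.0, "r_um": 20.0,
                "target_id": range(len(labels)), "target_label": labels}),
            n_outputs=len(labels))

    def test_four_of_ten_is_preferring(self):
        fractions, preferring = target_fractions(
            self._profile(["5P-NP"] * 4 + ["BC"] * 6))
        assert fractions["5P-NP"] == pytest.approx(0.4)
        assert preferring

    def test_exactly_thirty_percent_preferring_under_inclusive_rule(self):
        profile = self._profile(["5P-NP"] * 3 + ["BC"] * 7)
        _, inclusive = target_fractions(profile)
        _, strict = target_fractions(profile, strict=True)
        assert inclusive and not strict

    def test_fractions_sum_to_one(self):
        fractions, _ = target_fractions(
            self._profile(["5P-NP", "BC", "MC", "23P", "BC"]))
        assert fractions.sum() == pytest.approx(1.0)

    def test_unlabelled_profile_raises(self):
        profile = TargetingProfile(
            records=pd.DataFrame({"phi_deg": [90.0], "r_um": [10.0],
                                  "target_id": [1]}),
            n_outputs=1)
        with pytest.raises(ValueError):
            target_fractions(profile)


class TestFisher:
    def test_printed_chandelier_table_is_highly_significant(self):
        result = fisher_enrichment(16, 4, 0, 20)
        assert result.p_two_tailed < 1e-5
        assert abs(result.p_two_tailed
                   - fisher_two_tailed_enumeration(16, 4, 0, 20)) < 1e-12

    def test_symmetric_table_p_is_one(self):
        assert fisher_enrichment(10, 10, 10, 10).p_two_tailed == pytest.approx(1.0)

    def test_two_by_two_identity_table(self):
        assert fisher_enrichment(1, 0, 0, 1).p_two_tailed == pytest.approx(1.0)

    def test_matches_enumeration_on_margin_grid(self):
        rng = split_rng(0, 31)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 100, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_enrichment(int(a), int(b), int(c), int(d)).p_two_tailed
            p_oracle = fisher_two_tailed_enumeration(int(a), int(b), int(c), int(d))
            assert abs(p - p_oracle) < 1e-10

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 5, 5)


class TestProofreadingAndTruncation:
    def test_identical_tables(self):
        d = proofreading_deltas({1, 2, 3}, {1, 2, 3})
        assert (d["removed"], d["added"], d["maintained"]) == (0.0, 0.0, 1.0)

    def test_disjoint_tables(self):
        d = proofreading_deltas({1, 2}, {3, 4})
        assert (d["removed"], d["added"], d["maintained"]) == (1.0, 1.0, 0.0)

    def test_partial_overlap(self):
        d = proofreading_deltas({1, 2, 3, 4}, {3, 4, 5})
        assert d["removed"] == pytest.approx(0.5)
        assert d["added"] == pytest.approx(1.0 / 3.0)
        assert d["maintained"] == pytest.approx(0.5)

    def test_empty_both_raises(self):
        with pytest.raises(ValueError):
            proofreading_deltas(set(), set())

    def test_radial_extent_constant_distances(self):
        xyz = np.array([[10_000.0, 0, 0], [0, 10_000.0, 0], [0, 0, 10_000.0]])
        assert radial_extent(xyz, np.zeros(3)) == pytest.approx(10.0)

    def test_radial_extent_linear_interpolation(self):
        xyz = np.zeros((100, 3))
        xyz[:, 0] = np.arange(1, 101) * 1000.0
        assert radial_extent(xyz, np.zeros(3)) == pytest.approx(97.03)

    @given(st.floats(0.5, 4.0))
    @settings(deadline=None, max_examples=20)
    def test_radial_extent_homogeneity(self, scale):
        rng = split_rng(2, 32)
        xyz = rng.uniform(-50_000, 50_000, size=(30, 3))
        base = radial_extent(xyz, np.zeros(3))
        assert radial_extent(xyz * scale, np.zeros(3)) == pytest.approx(
            base * scale, rel=1e-9)

    def test_truncation_extremes_and_planted_half(self):
        extents = [100.0, 120.0, 140.0]
        assert truncation_estimate(extents, [500.0, 600.0]) == 0.0
        assert truncation_estimate(extents, [0.0, 0.0]) == 1.0
        borders = [60.0] * 5 + [500.0] * 5      # half below the median (120)
        assert truncation_estimate(extents, borders) == pytest.approx(0.5)


class TestDensityMap:
    def test_five_cells_in_one_bin_is_2000_per_mm2(self):
        pred = pd.Series(["BC"] * 5, index=pd.Index(range(5), name="cell_id"))
        pos = pd.DataFrame({"x_nm": [10_000.0] * 5, "z_nm": [10_000.0] * 5},
                           index=pred.index)
        grids = subclass_density_map(pred, pos, bin_um=50.0)
        assert grids["BC"].to_numpy().max() == pytest.approx(2000.0)

    def test_totals_conserved(self):
        rng = split_rng(3, 33)
        n = 200
        pred = pd.Series(rng.choice(["BC", "MC"], n),
                         index=pd.Index(range(n), name="cell_id"))
        pos = pd.DataFrame({"x_nm": rng.uniform(0, 4e5, n),
                            "z_nm": rng.uniform(0, 4e5, n)}, index=pred.index)
        grids = subclass_density_map(pred, pos, bin_um=50.0)
        bin_area_mm2 = 0.05 ** 2
        total = sum(g.to_numpy().sum() * bin_area_mm2 for g in grids.values())
        assert total == pytest.approx(n)


def test_chandelier_search_end_to_end():
    """Planted chandelier cells drawn from a common feature mode are
    retrieved by nearest-neighbour search at far above the hypergeometric
    null."""
    rng = split_rng(4, 34)
    n_background = 94
    n_chandelier = 6
    X = rng.normal(size=(n_background + n_chandelier, 13))
    mode = rng.normal(size=13)
    mode = 6.0 * mode / np.linalg.norm(mode)
    X[n_background:] += mode
    ids = pd.Index(np.arange(100), name="cell_id")
    df = pd.DataFrame(X, index=ids)
    chandeliers = set(range(n_background, n_background + n_chandelier))

    query = n_background     # one planted chandelier
    hits = nearest_neighbors(df, query, k=20)
    n_hits = sum(h in chandeliers for h in hits)
    assert n_hits == n_chandelier - 1
    misses = (n_chandelier - 1) - n_hits
    result = fisher_enrichment(n_hits, 20 - n_hits,
                               misses, (len(df) - 1 - 20) - misses)
    assert result.p_two_tailed < 0.01
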