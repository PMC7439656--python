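"""Encodings: CoIED centroid, weighted sampling, membership vectors, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyord import (
    ConfigurationError,
    EncodingMap,
    OrdinalScale,
    SEVERITY,
    baseline_encode,
    build_coied_map,
    build_membership_map,
    coied,
    fuzzify_from_points,
    membership_encode,
    weighted_sampling_encode,
)
from fuzzyord.fuzzify import FuzzySet


def point_mass(level, x):
    return fuzzify_from_points([x], level)


def weights_set(level, mapping):
    grid = np.arange(101)
    w = np.zeros(101)
    for x, v in mapping.items():
        w[x] = v
    return FuzzySet(level, grid, w)


class TestCoied:
    def test_uniform_set_centroid_is_midrange(self):
        f = FuzzySet("x", np.arange(101), np.ones(101))
        assert coied(f) == pytest.approx(50.0)

    def test_point_mass_is_identity(self):
        assert coied(point_mass("x", 42)) == 42.0

    def test_weighted_two_point_example(self):
        f = weights_set("x", {10: 1.0, 20: 3.0})
        assert coied(f) == pytest.approx(17.5)

    @settings(max_examples=50, derandomize=True)
    @given(
        xs=st.lists(st.integers(0, 100), min_size=1, max_size=10, unique=True),
        c=st.floats(0.1, 50.0),
    )
    def test_scale_invariance_and_bounds(self, xs, c):
        f = weights_set("x", {x: 1.0 + (x % 3) for x in xs})
        scaled = FuzzySet("x", f.grid, f.raw_weight * c)
        assert coied(scaled) == pytest.approx(coied(f), rel=1e-12)
        lo, hi = f.support()
        assert lo <= coied(f) <= hi


class TestCoiedMap:
    def test_monotone_point_masses_flagged_order_preserving(self, scale):
        sets = {v: point_mass(v, x) for v, x in zip(scale, (0, 25, 50, 75, 100))}
        m = build_coied_map(sets, scale)
        assert [m.per_level[v] for v in scale] == [0, 25, 50, 75, 100]
        assert m.order_preserving is True

    def test_inversion_detected(self, scale):
        sets = {v: point_mass(v, x) for v, x in zip(scale, (0, 60, 30, 75, 100))}
        assert build_coied_map(sets, scale).order_preserving is False

    def test_identical_sets_are_non_strictly_preserving(self, scale):
        sets = {v: weights_set(v, {10: 1.0, 30: 1.0}) for v in scale}
        m = build_coied_map(sets, scale)
        assert len(set(m.per_level.values())) == 1
        assert m.order_preserving is True

    def test_missing_level_raises(self, scale):
        sets = {v: point_mass(v, 10) for v in list(scale)[:-1]}
        with pytest.raises(ConfigurationError, match="Extreme"):
            build_coied_map(sets, scale)


class TestWeightedSampling:
    def test_point_mass_is_deterministic_in_both_modes(self):
        sets = {"Mild": point_mass("Mild", 30)}
        col = ["Mild"] * 8
        for mode in ("per_cell", "per_label"):
            out = weighted_sampling_encode(col, sets, rng_seed=0, mode=mode)
            np.testing.assert_array_equal(out, 30.0)

    def test_same_seed_reproduces_different_seed_varies(self, scale):
        sets = {v: weights_set(v, {10: 1.0, 50: 1.0, 90: 1.0}) for v in scale}
        col = list(scale) * 20
        a = weighted_sampling_encode(col, sets, rng_seed=7, scale=scale)
        b = weighted_sampling_encode(col, sets, rng_seed=7, scale=scale)
        c = weighted_sampling_encode(col, sets, rng_seed=8, scale=scale)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_per_label_reuses_one_draw_per_level(self, scale):
        sets = {v: weights_set(v, {10: 1.0, 50: 1.0, 90: 1.0}) for v in scale}
        col = ["Mild"] * 50 + ["Severe"] * 50
        out = weighted_sampling_encode(col, sets, rng_seed=3, mode="per_label", scale=scale)
        assert len(set(out[:50])) == 1 and len(set(out[50:])) == 1

    def test_frequencies_match_binomial_oracle(self):
        # p uniform on {5, 7}: over 10,000 draws, freq(5) within 0.5 +/- 3 sigma
        sets = {"Mild": weights_set("Mild", {5: 1.0, 7: 1.0})}
        out = weighted_sampling_encode(["Mild"] * 10_000, sets, rng_seed=11)
        freq5 = float(np.mean(out == 5))
        assert abs(freq5 - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_outputs_stay_in_support(self):
        sets = {"Mild": weights_set("Mild", {5: 1.0, 7: 3.0, 9: 1.0})}
        out = weighted_sampling_encode(["Mild"] * 500, sets, rng_seed=5)
        assert set(out) <= {5.0, 7.0, 9.0}

    def test_overlapping_supports_can_reverse_within_a_row(self):
        """Ordered centroids do not guarantee ordered draws row by row."""
        mild = weights_set("Mild", {20: 1.0, 60: 1.0})  # centroid 40
        severe = weights_set("Severe", {30: 1.0, 70: 1.0})  # centroid 50
        sets = {"Mild": mild, "Severe": severe}
        assert coied(mild) < coied(severe)
        n = 200
        x1 = weighted_sampling_encode(["Mild"] * n, sets, rng_seed=42)
        x2 = weighted_sampling_encode(["Severe"] * n, sets, rng_seed=43)
        assert np.any(x2 < x1)  # at least one row reversed under these seeds

    def test_missing_fuzzy_set_raises(self):
        with pytest.raises(ConfigurationError):
            weighted_sampling_encode(["Mild"], {}, rng_seed=0)


class TestMembership:
    def test_disjoint_supports_degenerate_to_one_hot(self, scale):
        sets = {v: point_mass(v, x) for v, x in zip(scale, (5, 25, 50, 75, 95))}
        for i, v in enumerate(scale):
            vec = membership_encode(v, sets, scale)
            expected = np.zeros(5)
            expected[i] = 1.0
            np.testing.assert_array_equal(vec, expected)

    @settings(max_examples=30, derandomize=True)
    @given(data=st.data())
    def test_one_hot_degeneration_property(self, data):
        """Random pairwise-disjoint supports reproduce one-hot exactly."""
        k = data.draw(st.integers(2, 5))
        scale = OrdinalScale(tuple(f"L{i}" for i in range(k)))
        # carve [0, 100] into k disjoint blocks and place random support in each
        edges = np.linspace(0, 101, k + 1).astype(int)
        sets = {}
        for i, v in enumerate(scale):
            lo, hi = edges[i], edges[i + 1] - 1
            xs = data.draw(
                st.lists(st.integers(lo, hi), min_size=1, max_size=4, unique=True)
            )
            sets[v] = weights_set(v, {x: float(1 + j) for j, x in enumerate(xs)})
        for i, v in enumerate(scale):
            vec = membership_encode(v, sets, scale)
            expected = np.zeros(k)
            expected[i] = 1.0
            np.testing.assert_array_equal(vec, expected)

    def test_overlap_reads_other_levels_membership(self):
        scale = OrdinalScale(("v1", "v2"))
        s1 = weights_set("v1", {10: 5.0})
        s2 = weights_set("v2", {10: 2.0, 30: 5.0})  # membership 0.4 at 10
        vec = membership_encode("v1", {"v1": s1, "v2": s2}, scale)
        np.testing.assert_allclose(vec, [1.0, 0.4])

    def test_single_level_scale(self):
        scale = OrdinalScale(("only",))
        vec = membership_encode("only", {"only": point_mass("only", 40)}, scale)
        np.testing.assert_array_equal(vec, [1.0])

    def test_argmax_tie_breaks_to_smallest_grid_value(self):
        s = weights_set("v", {10: 2.0, 20: 2.0})
        from fuzzyord.encode import modal_value

        assert modal_value(s) == 10.0


class TestBaselines:
    def test_ordinal_rank(self, scale):
        out = baseline_encode(["Absent", "Mild", "Extreme"], scale, "ordinal_rank")
        np.testing.assert_array_equal(out, [0.0, 1.0, 4.0])

    def test_one_hot(self, scale):
        out = baseline_encode(["Mild"], scale, "one_hot")
        np.testing.assert_array_equal(out, [[0, 1, 0, 0, 0]])

    def test_rank_hot_staircase(self, scale):
        out = baseline_encode(list(scale), scale, "rank_hot")
        np.testing.assert_array_equal(out[2], [1, 1, 1, 0, 0])  # Moderate
        # consecutive levels differ in exactly one component
        for i in range(4):
            assert int(np.sum(out[i] != out[i + 1])) == 1

    def test_unknown_level_raises(self, scale):
        with pytest.raises(ValueError):
            baseline_encode(["Bogus"], scale, "ordinal_rank")


class TestEncodingMapSerialization:
    def test_coied_map_round_trip(self, scale):
        sets = {v: point_mass(v, x) for v, x in zip(scale, (0, 25, 50, 75, 100))}
        m = build_coied_map(sets, scale)
        again = EncodingMap.from_json(m.to_json())
        assert again.kind == "coied"
        assert again.per_level == {v: float(m.per_level[v]) for v in scale}
        assert again.order_preserving is True

    def test_membership_map_round_trip(self, scale):
        sets = {v: point_mass(v, x) for v, x in zip(scale, (0, 25, 50, 75, 100))}
        m = build_membership_map(sets, scale)
        again = EncodingMap.from_json(m.to_json())
        np.testing.assert_array_equal(
            np.asarray(again.per_level["Mild"]), np.asarray(m.per_level["Mild"])
        )
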