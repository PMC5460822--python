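"""Co-occurrence and run-length matrices against enumeration oracles,
plus the 16 feature formulas on hand-worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumortex import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    GreyLevelConfig,
    build_cm,
    build_rlm,
    cm_features,
    extract_features,
    quantize,
    rlm_features,
)
from tumortex.texture import CooccurrenceMatrix, RunLengthMatrix

from conftest import brute_force_cm, brute_force_rlm, make_quantized, random_quantized


def test_direction_set_covers_26_neighborhood_antipodally():
    assert len(DIRECTIONS_13) == 13
    offsets = set(DIRECTIONS_13) | {tuple(-c for c in d) for d in DIRECTIONS_13}
    assert len(offsets) == 26
    assert all(max(abs(c) for c in d) == 1 for d in offsets)


class TestCooccurrence:
    def test_two_voxel_pair_counted_in_both_orders(self):
        q = make_quantized(np.array([1, 2]).reshape(2, 1, 1), n_levels=2)
        cm = build_cm(q)
        np.testing.assert_array_equal(cm.counts, [[0, 1], [1, 0]])
        np.testing.assert_allclose(cm.probabilities, [[0, 0.5], [0.5, 0]])

    def test_constant_cube_concentrates_at_diagonal_cell(self):
        q = make_quantized(np.full((3, 3, 3), 2, dtype=int), n_levels=3)
        cm = build_cm(q)
        assert cm.probabilities[1, 1] == 1.0
        assert cm.counts.sum() == cm.counts[1, 1]

    def test_symmetry_and_unit_mass_on_random_volumes(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            q = random_quantized(rng)
            try:
                cm = build_cm(q)
            except ValueError:
                continue  # scattered mask with no adjacent pair
            np.testing.assert_array_equal(cm.counts, cm.counts.T)
            assert cm.probabilities.sum() == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 30:
            q = random_quantized(rng)
            expected = brute_force_cm(q.levels, q.mask.values, q.n_levels)
            if expected.sum() == 0:
                continue
            np.testing.assert_array_equal(build_cm(q).counts, expected)
            checked += 1

    def test_scattered_mask_without_adjacent_pair_rejected(self):
        levels = np.zeros((5, 5, 1), dtype=int)
        levels[0, 0, 0] = 1
        levels[4, 4, 0] = 2
        q = make_quantized(levels, n_levels=2)
        with pytest.raises(ValueError, match="26-adjacent"):
            build_cm(q)


class TestCMFeatures:
    def test_degenerate_distribution(self):
        q = make_quantized(np.full((3, 3, 3), 2, dtype=int), n_levels=3)
        f = cm_features(build_cm(q))
        assert f["Entropy"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Dissimilarity"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["Uniformity"] == 1.0

    def test_two_voxel_example_exact(self):
        q = make_quantized(np.array([1, 2]).reshape(2, 1, 1), n_levels=2)
        f = cm_features(build_cm(q))
        assert f["Entropy"] == pytest.approx(math.log(2), abs=1e-15)
        assert f["Contrast"] == 1.0
        assert f["Dissimilarity"] == 1.0
        assert f["Homogeneity"] == 0.5
        assert f["Uniformity"] == 0.5

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_uniform_distribution_attains_maximum_entropy(self, n):
        counts = np.ones((n, n), dtype=np.int64)
        cm = CooccurrenceMatrix(counts, counts / counts.sum(), n)
        f = cm_features(cm)
        assert f["Entropy"] == pytest.approx(2 * math.log(n))
        assert f["Uniformity"] == pytest.approx(1 / n**2)

    def test_unnormalized_input_rejected(self):
        counts = np.array([[2, 0], [0, 2]], dtype=np.int64)
        bad = CooccurrenceMatrix(counts, counts.astype(float), 2)
        with pytest.raises(ValueError, match="sum to 1"):
            cm_features(bad)

    def test_feature_bounds_on_random_volumes(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = random_quantized(rng)
            try:
                f = cm_features(build_cm(q))
            except ValueError:
                continue
            assert f["Entropy"] >= 0
            assert 0 < f["Homogeneity"] <= 1
            assert 1 / q.n_levels**2 <= f["Uniformity"] <= 1


class TestRunLength:
    def test_single_voxel_one_run_per_direction(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[1, 1, 1] = 2
        rlm = build_rlm(make_quantized(levels, n_levels=3))
        assert rlm.n_runs == 13
        assert rlm.counts[1, 0] == 13
        assert rlm.max_run_length == 1

    def test_three_voxel_line_enumerated_exactly(self):
        # x-axis: runs (level 1, len 2), (level 2, len 1); the other 12
        # directions each contribute three length-1 runs.
        q = make_quantized(np.array([1, 1, 2]).reshape(3, 1, 1), n_levels=2)
        rlm = build_rlm(q)
        assert rlm.counts[0, 0] == 24  # level 1, length 1
        assert rlm.counts[0, 1] == 1   # level 1, length 2
        assert rlm.counts[1, 0] == 13  # level 2, length 1
        assert rlm.n_runs == 38

    def test_voxel_count_conservation_on_random_volumes(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q = random_quantized(rng)
            rlm = build_rlm(q)
            j = np.arange(1, rlm.max_run_length + 1)
            assert (rlm.counts * j).sum() == 13 * q.n_masked
            # M is tight: the longest-run column is populated
            assert rlm.counts[:, -1].any()

    def test_matches_brute_force_line_walking_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            q = random_quantized(rng)
            expected = brute_force_rlm(q.levels, q.mask.values, q.n_levels)
            np.testing.assert_array_equal(build_rlm(q).counts, expected)

    def test_empty_mask_rejected(self):
        from tumortex.volume import QuantizedVolume, ROIMask

        q = QuantizedVolume(
            np.zeros((2, 2, 2), dtype=np.int32), 2,
            ROIMask(np.zeros((2, 2, 2), bool), (1.0, 1.0, 1.0)),
        )
        with pytest.raises(ValueError, match="nonempty mask"):
            build_rlm(q)


class TestRLMFeatures:
    def test_single_voxel_feature_values(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[1, 1, 1] = 2
        f = rlm_features(build_rlm(make_quantized(levels, n_levels=3)))
        assert f["SRE"] == 1.0
        assert f["LRE"] == 1.0
        assert f["LGRE"] == pytest.approx(1 / 4)
        assert f["HGRE"] == pytest.approx(4)
        assert f["GLNU"] == pytest.approx(13)
        assert f["RLNU"] == pytest.approx(13)
        assert f["RPC"] == 1.0

    def test_three_voxel_line_features_exact(self):
        q = make_quantized(np.array([1, 1, 2]).reshape(3, 1, 1), n_levels=2)
        f = rlm_features(build_rlm(q))
        assert f["SRE"] == pytest.approx(37.25 / 38, abs=1e-15)
        assert f["LRE"] == pytest.approx(41 / 38, abs=1e-15)
        assert f["RPC"] == pytest.approx(38 / 39, abs=1e-15)

    def test_sre_le_one_le_lre_with_equality_iff_unit_runs(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            q = random_quantized(rng)
            rlm = build_rlm(q)
            f = rlm_features(rlm)
            assert f["SRE"] <= 1.0 + 1e-12
            assert f["LRE"] >= 1.0 - 1e-12
            if rlm.max_run_length == 1:
                assert f["SRE"] == 1.0 and f["LRE"] == 1.0

    def test_zero_run_matrix_rejected(self):
        empty = RunLengthMatrix(np.zeros((2, 1), dtype=np.int64), 2)
        with pytest.raises(ValueError, match="at least one run"):
            rlm_features(empty)


class TestExtractFeatures:
    def test_sixteen_named_finite_values(self, test_phantom):
        from tumortex import build_configuration_grid, default_grey_configs, default_spatial_configs

        grid = build_configuration_grid(
            test_phantom,
            default_spatial_configs((64,), (1.0,)),
            default_grey_configs((16,)),
        )
        f = extract_features(grid[0])
        assert tuple(f) == FEATURE_NAMES
        assert len(f) == 16
        assert all(np.isfinite(v) for v in f.values())

    def test_constant_roi_degenerate_values(self):
        q = make_quantized(np.full((4, 4, 4), 1, dtype=int), n_levels=16)
        f = extract_features(q)
        assert f["Entropy"] == 0.0 and f["Uniformity"] == 1.0
        assert f["LGRE"] == 1.0 and f["HGRE"] == 1.0
        assert f["LRE"] > 1.0  # the 4-long axis runs dominate


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_property_both_matrices_match_oracles(data):
    """CM and RLM equal brute-force enumeration on random small volumes."""
    seed = data.draw(st.integers(0, 2**31 - 1))
    q = random_quantized(np.random.default_rng(seed))
    rlm_expected = brute_force_rlm(q.levels, q.mask.values, q.n_levels)
    np.testing.assert_array_equal(build_rlm(q).counts, rlm_expected)
    cm_expected = brute_force_cm(q.levels, q.mask.values, q.n_levels)
    if cm_expected.sum():
        np.testing.assert_array_equal(build_cm(q).counts, cm_expected)


class TestQuantizationMonotonicity:
    def test_entropy_nondecreasing_uniformity_nonincreasing_in_n(self, test_phantom):
        """Nested bins make the coarse pair distribution an aggregation of
        the fine one, so CM entropy grows and uniformity shrinks with N."""
        entropies, uniformities = [], []
        for n in (16, 32, 64):
            q = quantize(test_phantom.image, test_phantom.mask, GreyLevelConfig(n))
            f = cm_features(build_cm(q))
            entropies.append(f["Entropy"])
            uniformities.append(f["Uniformity"])
        assert entropies[0] <= entropies[1] <= entropies[2]
        assert uniformities[0] >= uniformities[1] >= uniformities[2]


class TestGreyLevelReversal:
    @staticmethod
    def _reverse(q):
        levels = q.levels.copy()
        inside = q.mask.values
        levels[inside] = q.n_levels + 1 - levels[inside]
        return make_quantized(levels, q.n_levels, mask=inside)

    def test_reversal_invariant_features(self):
        rng = np.random.default_rng(23)
        invariant = ["Contrast", "Dissimilarity", "Homogeneity", "Entropy",
                     "Uniformity", "SRE", "LRE", "RPC", "GLNU", "RLNU"]
        q = random_quantized(rng, max_side=6, max_levels=4)
        f = extract_features(q)
        f_rev = extract_features(self._reverse(q))
        for name in invariant:
            assert f[name] == pytest.approx(f_rev[name], rel=1e-12), name

    def test_lgre_hgre_swap_on_worked_example(self):
        # runs at levels 1 and 3 of a 3-level volume: reversal maps 1<->3
        q = make_quantized(np.array([1, 1, 3]).reshape(3, 1, 1), n_levels=3)
        f = extract_features(q)
        f_rev = extract_features(self._reverse(q))
        assert f["LGRE"] != pytest.approx(f["HGRE"])
        # the reversed volume's grey-level moments, from the oracle RLM
        expect = _swap_expect(q)
        assert f_rev["LGRE"] == pytest.approx(expect["LGRE"], rel=1e-12)
        assert f_rev["HGRE"] == pytest.approx(expect["HGRE"], rel=1e-12)


def _swap_expect(q):
    """Expected LGRE/HGRE after reversal, computed from the reversed RLM directly."""
    levels = q.levels.copy()
    inside = q.mask.values
    levels[inside] = q.n_levels + 1 - levels[inside]
    rlm = brute_force_rlm(levels, inside, q.n_levels)
    r = rlm.astype(float)
    nr = r.sum()
    i2 = (np.arange(1, q.n_levels + 1) ** 2)[:, None]
    return {"LGRE": (r / i2).sum() / nr, "HGRE": (r * i2).sum() / nr}
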