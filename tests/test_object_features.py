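"""Object-level features: moments, LBP, PC ratio, neighborhoods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emsynapse.object_features import (
    MomentAccumulator,
    NeighborhoodSpec,
    OBJECT_FEATURE_NAMES,
    compute_object_features,
    lbp_histogram,
    object_neighborhood,
    principal_component_ratio,
    summary_statistics,
)
from emsynapse.volume import AnisotropicVolume

VS = (45.0, 4.5, 4.5)


def stats_oracle(values):
    """Direct-formula oracle in extended precision."""
    v = np.asarray(values, dtype=np.longdouble)
    n = v.size
    mean = v.mean()
    d = v - mean
    m2, m3, m4 = (d ** 2).mean(), (d ** 3).mean(), (d ** 4).mean()
    var = (d ** 2).sum() / (n - 1) if n > 1 else 0.0
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 if m2 > 0 else 0.0
    return float(mean), float(var), float(skew), float(kurt)


class TestSummaryStatistics:
    def test_constant_list_degenerates_to_zero(self):
        mean, var, skew, kurt = summary_statistics([4.0, 4.0, 4.0])
        assert (mean, var, skew, kurt) == (4.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic_mean(self):
        assert summary_statistics([0, 0, 0, 1])[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_extended_precision_oracle(self, seed):
        values = np.random.default_rng(seed).normal(3, 2, size=101)
        got = summary_statistics(values)
        want = stats_oracle(values)
        assert got == pytest.approx(want, rel=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=60
        ),
        split=st.integers(1, 59),
    )
    def test_merge_invariant_for_arbitrary_splits(self, values, split):
        """Merging moment accumulators over any split of the data matches
        the single-pass result."""
        values = np.asarray(values)
        split = min(split, len(values) - 1)
        whole = MomentAccumulator().update(values).statistics()
        acc = MomentAccumulator().update(values[:split])
        acc.merge(MomentAccumulator().update(values[split:]))
        merged = acc.statistics()
        for w, m in zip(whole, merged):
            assert m == pytest.approx(w, rel=1e-8, abs=1e-8)

    def test_blockwise_merge_equals_whole_computation(self, rng):
        values = rng.normal(10, 3, size=1000)
        whole = MomentAccumulator().update(values).statistics()
        acc = MomentAccumulator()
        for chunk in np.array_split(values, 7):
            acc.merge(MomentAccumulator().update(chunk))
        merged = acc.statistics()
        assert merged == pytest.approx(whole, rel=1e-9)


class TestObjectNeighborhood:
    def test_zero_radii_empty(self):
        mask = np.zeros((3, 5, 5), bool)
        mask[1, 2, 2] = True
        assert not object_neighborhood(mask, NeighborhoodSpec((0, 0, 0))).any()

    def test_single_voxel_in_slice_neighbors(self):
        mask = np.zeros((3, 5, 5), bool)
        mask[1, 2, 2] = True
        nbh = object_neighborhood(mask, NeighborhoodSpec((1, 1, 0)))
        # Euclidean radius 1 in-plane: the 4-neighborhood, same slice only
        expect = np.zeros_like(mask)
        for dy, dx in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            expect[1, 2 + dy, 2 + dx] = True
        assert np.array_equal(nbh, expect)

    def test_neighborhood_never_overlaps_object(self, rng):
        mask = rng.random((4, 12, 12)) > 0.8
        if not mask.any():
            mask[0, 0, 0] = True
        nbh = object_neighborhood(mask, NeighborhoodSpec((3, 3, 1)))
        assert not (nbh & mask).any()

    def test_anisotropic_default_restricts_z(self):
        mask = np.zeros((5, 70, 70), bool)
        mask[2, 35, 35] = True
        nbh = object_neighborhood(mask)
        occupied_z = np.flatnonzero(nbh.any(axis=(1, 2)))
        assert occupied_z.tolist() == [1, 2, 3]  # 1 slice up/down

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            object_neighborhood(np.zeros((2, 2, 2), bool))


class TestLBP:
    def test_constant_region_single_bin(self):
        img = np.full((2, 6, 6), 5.0)
        region = np.ones_like(img, bool)
        hist = lbp_histogram(img, region)
        assert hist.shape == (10,)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1

    def test_histogram_normalized(self, rng):
        img = rng.random((3, 8, 8))
        region = rng.random((3, 8, 8)) > 0.4
        region[0, 0, 0] = True
        assert lbp_histogram(img, region).sum() == pytest.approx(1.0)

    def test_bright_center_pixel_hand_codes(self):
        # one bright pixel in a dark 3x3 slice; bits are set where neighbor
        # >= center.  The bright center sees 8 strictly darker samples (all
        # bits 0 -> bin 0); every dark pixel sees only samples >= itself
        # (all bits 1 -> 8 ones, uniform -> bin 8)
        img = np.zeros((1, 3, 3))
        img[0, 1, 1] = 10.0
        region = np.ones_like(img, bool)
        hist = lbp_histogram(img, region)
        counts = hist * 9
        assert counts[0] == pytest.approx(1)  # the bright center
        assert counts[8] == pytest.approx(8)  # its 8 neighbors

    def test_empty_region_gives_zero_histogram(self):
        hist = lbp_histogram(np.zeros((1, 4, 4)), np.zeros((1, 4, 4), bool))
        assert hist.shape == (10,) and not hist.any()


class TestPCRatio:
    def test_cube_at_isotropic_scaling_is_one(self):
        mask = np.ones((5, 5, 5), bool)
        assert principal_component_ratio(mask, (1, 1, 1)) == pytest.approx(1.0)

    def test_line_ratio_large_and_monotone_in_length(self):
        ratios = []
        for n in (5, 10, 20):
            mask = np.zeros((1, 1, n), bool)
            mask[0, 0, :] = True
            ratios.append(principal_component_ratio(mask, (1, 1, 1)))
        assert ratios[0] > 100  # epsilon-floored
        assert ratios[0] < ratios[1] < ratios[2]

    def test_invariant_under_axis_permutation(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 2:4, 3] = True
        r1 = principal_component_ratio(mask, (1, 1, 1))
        r2 = principal_component_ratio(mask.transpose(2, 0, 1), (1, 1, 1))
        assert r1 == pytest.approx(r2)

    def test_anisotropic_voxels_change_physical_ratio(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[:, 1, 1] = True
        mask[1, 1, 0] = mask[1, 1, 2] = True
        iso = principal_component_ratio(mask, (1, 1, 1))
        aniso = principal_component_ratio(mask, (10, 1, 1))
        assert aniso != pytest.approx(iso)

    def test_tiny_mask_degenerates_to_zero(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        assert principal_component_ratio(mask, VS) == 0.0


class TestComputeObjectFeatures:
    def _volume(self, rng, shape=(8, 80, 80)):
        return AnisotropicVolume(rng.normal(150, 10, shape), VS)

    def _mask(self, shape=(8, 80, 80)):
        mask = np.zeros(shape, bool)
        mask[3:5, 35:45, 35:45] = True
        return mask

    def test_vector_has_29_named_features(self, rng):
        vec = compute_object_features(self._volume(rng), self._mask())
        assert vec.shape == (29,)
        assert len(OBJECT_FEATURE_NAMES) == 29

    def test_candidates_computed_independently(self, rng):
        v = self._volume(rng)
        m1 = self._mask()
        m2 = np.zeros_like(m1)
        m2[1:3, 5:12, 5:12] = True
        a1 = compute_object_features(v, m1)
        a2 = compute_object_features(v, m2)
        # swapping processing order changes nothing
        b2 = compute_object_features(v, m2)
        b1 = compute_object_features(v, m1)
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)

    def test_constant_volume_degenerates(self):
        v = AnisotropicVolume(np.full((8, 80, 80), 100.0), VS)
        vec = compute_object_features(v, self._mask())
        named = dict(zip(OBJECT_FEATURE_NAMES, vec))
        assert named["variance"] == 0.0
        assert named["skewness"] == 0.0 and named["kurtosis"] == 0.0
        lbp = [named[f"lbp_{i}"] for i in range(10)]
        assert sum(b > 0 for b in lbp) == 1

    def test_crop_mask_with_origin_matches_full_mask(self, rng):
        v = self._volume(rng)
        full = self._mask()
        crop = full[3:5, 35:45, 35:45]
        a = compute_object_features(v, full)
        b = compute_object_features(v, crop, origin=(3, 35, 35))
        assert np.allclose(a, b)

    def test_neighborhood_features_sense_surrounding_context(self, rng):
        shape = (8, 80, 80)
        base = rng.normal(150, 5, shape)
        v1 = AnisotropicVolume(base, VS)
        surround = base.copy()
        surround[2:6, 30:50, 30:50] -= 60.0  # darken context, not the object
        mask = self._mask()
        surround[mask] = base[mask]
        v2 = AnisotropicVolume(surround, VS)
        f1 = compute_object_features(v1, mask)
        f2 = compute_object_features(v2, mask)
        named1 = dict(zip(OBJECT_FEATURE_NAMES, f1))
        named2 = dict(zip(OBJECT_FEATURE_NAMES, f2))
        assert named1["mean"] == pytest.approx(named2["mean"])
        assert named1["nbh_mean"] != pytest.approx(named2["nbh_mean"], abs=1.0)
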