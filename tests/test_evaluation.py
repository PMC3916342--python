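"""Detection matching and error-analysis morphometrics."""

import numpy as np
import pytest

from emsynapse.evaluation import (
    EvaluationReport,
    GroundTruthAnnotation,
    error_rates,
    match_detections,
    mean_xy_area,
    perforation_count,
    skeleton_size,
    z_range,
)

VS = (45.0, 4.5, 4.5)


def box_mask(shape, z0, z1, y0, y1, x0, x1):
    m = np.zeros(shape, bool)
    m[z0:z1, y0:y1, x0:x1] = True
    return m


class TestMatching:
    def test_point_inside_mask_matches_at_zero_tolerance(self):
        mask = box_mask((4, 10, 10), 1, 3, 2, 6, 2, 6)
        gt = GroundTruthAnnotation([[2, 4, 4]])
        rep = match_detections({0: mask}, gt, VS, tolerance_nm=0.0)
        assert rep.n_fn == 0 and rep.n_fp == 0 and rep.matches[0] == 0

    def test_no_candidates_all_false_negative(self):
        gt = GroundTruthAnnotation([[1, 1, 1], [2, 2, 2]])
        rep = match_detections({}, gt, VS)
        assert rep.n_fn == 2 and rep.n_fp == 0

    def test_one_to_one_matching_rule(self):
        mask = box_mask((4, 10, 10), 1, 2, 4, 6, 4, 6)
        gt = GroundTruthAnnotation([[1, 4, 4], [1, 5, 5]])
        rep = match_detections({0: mask}, gt, VS, tolerance_nm=100.0)
        matched = [v for v in rep.matches.values() if v is not None]
        assert len(matched) == 1 and rep.n_fn == 1

    def test_unmatched_candidate_is_false_positive(self):
        near = box_mask((4, 10, 10), 1, 2, 1, 3, 1, 3)
        far = box_mask((4, 10, 10), 3, 4, 7, 9, 7, 9)
        gt = GroundTruthAnnotation([[1, 2, 2]])
        rep = match_detections({0: near, 1: far}, gt, VS, tolerance_nm=50.0)
        assert rep.n_fp == 1 and rep.n_fn == 0

    def test_counts_conserved_and_order_invariant(self, rng):
        masks = {}
        for i in range(4):
            masks[i] = box_mask((6, 20, 20), i, i + 1, 4 * i, 4 * i + 3, 4 * i, 4 * i + 3)
        gt = GroundTruthAnnotation([[i, 4 * i + 1, 4 * i + 1] for i in range(3)])
        rep1 = match_detections(masks, gt, VS, 200.0)
        rep2 = match_detections(dict(reversed(list(masks.items()))), gt, VS, 200.0)
        matched = sum(v is not None for v in rep1.matches.values())
        assert rep1.n_fn == rep2.n_fn == len(gt) - matched
        assert rep1.matches == rep2.matches

    def test_crop_masks_with_origins(self):
        crop = np.ones((1, 2, 2), bool)
        gt = GroundTruthAnnotation([[3, 10, 10]])
        rep = match_detections({0: crop}, gt, VS, 0.0, candidate_origins={0: (3, 10, 10)})
        assert rep.n_fn == 0


class TestMorphometrics:
    def test_mean_area_constant_slices(self):
        mask = np.zeros((9, 10, 10), bool)
        mask[1:8, 2:4, 3:8] = True  # 10 voxels per slice over 7 slices
        assert mean_xy_area(mask) == pytest.approx(10.0)

    def test_mean_area_single_slice(self):
        mask = np.zeros((3, 10, 10), bool)
        mask[1, 2:7, 2:7] = True
        assert mean_xy_area(mask) == pytest.approx(25.0)

    def test_mean_area_central_five_of_seven(self):
        # slice areas 2,4,6,8,10,12,14 -> central five are 4..12, mean 8
        mask = np.zeros((7, 20, 20), bool)
        for i, area in enumerate([2, 4, 6, 8, 10, 12, 14]):
            mask[i, 0, :area] = True
        assert mean_xy_area(mask) == pytest.approx(8.0)

    def test_z_range_counts_occupied_slices_not_span(self):
        mask = np.zeros((10, 4, 4), bool)
        for z in (3, 4, 7):
            mask[z, 1, 1] = True
        assert z_range(mask) == 3

    def test_z_range_single_slice(self):
        mask = np.zeros((5, 4, 4), bool)
        mask[2, 1:3, 1:3] = True
        assert z_range(mask) == 1

    def test_skeleton_of_straight_line(self):
        mask = np.zeros((1, 15, 15), bool)
        mask[0, 7, 2:12] = True  # 10-voxel 1-wide line
        size = skeleton_size(mask, (45.0, 4.5, 4.5))
        # skeleton reproduces the line within +-1 voxel
        assert size == pytest.approx(10 * 4.5 * 45.0, abs=1 * 4.5 * 45.0)

    def test_skeleton_scales_linearly_with_lateral_voxel_size(self):
        mask = np.zeros((2, 12, 12), bool)
        mask[:, 5, 2:10] = True
        s1 = skeleton_size(mask, (45.0, 4.5, 4.5))
        s2 = skeleton_size(mask, (45.0, 9.0, 9.0))
        assert s2 == pytest.approx(2 * s1)

    def test_skeleton_additive_over_slices(self):
        one = np.zeros((1, 12, 12), bool)
        one[0, 5, 2:10] = True
        three = np.concatenate([one, one, one])
        assert skeleton_size(three, VS) == pytest.approx(3 * skeleton_size(one, VS))

    def test_perforation_counts_exactly_two_component_slices(self):
        mask = np.zeros((6, 10, 10), bool)
        mask[0, 2:4, 2:8] = True                       # 1 component
        for z in (1, 2, 3):                            # 2 components
            mask[z, 2:4, 2:4] = mask[z, 2:4, 6:8] = True
        mask[4, 2:3, 2:3] = mask[4, 2:3, 5:6] = mask[4, 2:3, 8:9] = True  # 3 comps
        assert perforation_count(mask) == 3
        assert perforation_count(mask, at_least=True) == 4

    def test_solid_object_has_no_perforation(self):
        assert perforation_count(box_mask((4, 6, 6), 1, 3, 1, 5, 1, 5)) == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mean_xy_area(np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            skeleton_size(np.zeros((2, 2, 2), bool), VS)


class TestErrorRates:
    def test_reference_arithmetic(self):
        # 28 missed and 16 false detections on 238 synapses
        rep = EvaluationReport(
            n_gt=238, n_detected=226, n_fn=28, n_fp=16,
            matches={i: (i if i < 210 else None) for i in range(238)},
        )
        fn, fp = error_rates(rep)
        assert fn == pytest.approx(28 / 238)
        assert fp == pytest.approx(16 / 238)
        assert round(fp * 100) == 7

    def test_zero_errors(self):
        rep = EvaluationReport(n_gt=2, n_detected=2, n_fn=0, n_fp=0, matches={0: 0, 1: 1})
        assert error_rates(rep) == (0.0, 0.0)

    def test_zero_ground_truth_undefined(self):
        rep = EvaluationReport(n_gt=0, n_detected=0, n_fn=0, n_fp=0, matches={})
        with pytest.raises(ValueError):
            error_rates(rep)
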