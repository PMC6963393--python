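import numpy as np
import pytest
from hypothesis import given, strategies as st

from iphquant import (
    ROIPointSet, ThresholdCriterion, Volume3D, compute_metrics,
    default_scm_roi, enforce_consecutive_slices, generate_subject,
    qualify_plaque, sample_muscle_reference, segment_iph, threshold_iph,
)
from iphquant.phantom import IPHSpec, NoiseSpec, PhantomConfig
from iphquant.segment_semiauto import ReferenceIntensity

from oracles import segment_iph_naive, threshold_loop


def _volume(data, spacing=(0.31, 0.31, 1.0)):
    return Volume3D(np.asarray(data, float), spacing=spacing)


class TestMuscleReference:
    def test_mean_of_three_points(self):
        data = np.zeros((8, 8, 4))
        pts = [(1, 1, 1), (2, 2, 1), (3, 3, 1)]
        for p, v in zip(pts, (100.0, 110.0, 120.0)):
            data[p] = v
        ref = sample_muscle_reference(_volume(data), ROIPointSet(points=pts))
        assert ref.mean == pytest.approx(110.0)
        assert ref.n_points == 3

    def test_identical_values_give_that_value(self):
        data = np.full((8, 8, 4), 73.0)
        ref = sample_muscle_reference(
            _volume(data), ROIPointSet(points=[(0, 0, 0), (1, 1, 1), (2, 2, 2)]))
        assert ref.mean == pytest.approx(73.0)

    def test_two_points_rejected_under_strict_policy(self):
        data = np.full((8, 8, 4), 1.0)
        with pytest.raises(ValueError, match="exactly 3"):
            sample_muscle_reference(_volume(data),
                                    ROIPointSet(points=[(0, 0, 0), (1, 1, 1)]))

    def test_nonpositive_mean_rejected(self):
        data = np.zeros((8, 8, 4))
        with pytest.raises(ValueError, match="> 0"):
            sample_muscle_reference(
                _volume(data), ROIPointSet(points=[(0, 0, 0), (1, 1, 1), (2, 2, 2)]))


class TestQualifyPlaque:
    @pytest.mark.parametrize("thicknesses,expected", [
        ((1.8, 2.1, 2.3, 1.9), True),    # adjacent pair both > 2
        ((2.1, 1.9, 2.1, 1.9), False),   # no adjacent qualifying pair
        ((2.0, 2.0), False),             # strict inequality at the 2 mm cut
        ((2.5,), False),                 # single slice can never qualify
        ((2.01, 2.01), True),
    ])
    def test_two_consecutive_slice_rule(self, thicknesses, expected):
        assert qualify_plaque(thicknesses) is expected

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            qualify_plaque([2.0, -0.1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            qualify_plaque([])


class TestThresholdIPH:
    def test_uniform_plaque_below_higher_thresholds(self):
        data = np.full((6, 6, 4), 160.0)
        plaque = np.zeros((6, 6, 4), bool)
        plaque[1:5, 1:5, :] = True
        ref = ReferenceIntensity(mean=100.0, point_values=(100.0,) * 3, n_points=3)
        vol = _volume(data)
        assert np.array_equal(threshold_iph(vol, plaque, ref, ThresholdCriterion(1.5)),
                              plaque)
        assert not threshold_iph(vol, plaque, ref, ThresholdCriterion(1.75)).any()
        assert not threshold_iph(vol, plaque, ref, ThresholdCriterion(2.0)).any()

    def test_exact_boundary_value_excluded_when_strict(self):
        data = np.full((4, 4, 2), 150.0)
        plaque = np.ones((4, 4, 2), bool)
        ref = ReferenceIntensity(mean=100.0, point_values=(100.0,) * 3, n_points=3)
        strict = threshold_iph(_volume(data), plaque, ref, ThresholdCriterion(1.5))
        lenient = threshold_iph(_volume(data), plaque, ref,
                                ThresholdCriterion(1.5, strict=False))
        assert not strict.any()
        assert lenient.all()

    def test_matches_voxelwise_loop_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.uniform(0, 300, (10, 9, 5))
        plaque = rng.random((10, 9, 5)) > 0.4
        ref = ReferenceIntensity(mean=110.0, point_values=(110.0,) * 3, n_points=3)
        got = threshold_iph(_volume(data), plaque, ref, ThresholdCriterion(1.75))
        want = threshold_loop(data, plaque, 1.75 * 110.0)
        np.testing.assert_array_equal(got, want)

    def test_shape_mismatch_rejected(self):
        ref = ReferenceIntensity(mean=100.0, point_values=(100.0,) * 3, n_points=3)
        with pytest.raises(ValueError, match="shape"):
            threshold_iph(_volume(np.zeros((4, 4, 4))), np.zeros((5, 4, 4), bool),
                          ref, ThresholdCriterion(1.5))


class TestConsecutiveSlices:
    def test_single_slice_component_removed(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 3] = True
        assert not enforce_consecutive_slices(mask).any()

    def test_two_adjacent_slice_component_retained(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 3:5] = True
        np.testing.assert_array_equal(enforce_consecutive_slices(mask), mask)

    def test_disjoint_single_slice_components_both_removed(self):
        mask = np.zeros((8, 8, 10), bool)
        mask[2:4, 2:4, 3] = True
        mask[2:4, 2:4, 7] = True
        assert not enforce_consecutive_slices(mask).any()

    def test_mixed_components_filtered_independently(self):
        mask = np.zeros((10, 10, 8), bool)
        mask[1:3, 1:3, 2:4] = True   # spans slices {2,3}: keep
        mask[7:9, 7:9, 5] = True     # single slice: drop
        out = enforce_consecutive_slices(mask)
        assert out[1:3, 1:3, 2:4].all()
        assert not out[7:9, 7:9, 5].any()

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        mask = rng.random((12, 12, 8)) > 0.75
        once = enforce_consecutive_slices(mask)
        np.testing.assert_array_equal(enforce_consecutive_slices(once), once)

    def test_min_slices_below_one_rejected(self):
        with pytest.raises(ValueError, match="min_slices"):
            enforce_consecutive_slices(np.zeros((4, 4, 4), bool), min_slices=0)

    def test_whole_mask_scope(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1, 1, 2] = True
        mask[4, 4, 3] = True   # two single-slice components on adjacent slices
        assert not enforce_consecutive_slices(mask, scope="component").any()
        np.testing.assert_array_equal(
            enforce_consecutive_slices(mask, scope="mask"), mask)


class TestComputeMetrics:
    def test_ten_voxel_volume(self):
        mask = np.zeros((8, 8, 4), bool)
        mask[0, 0:5, 1] = True
        mask[0, 0:5, 2] = True
        m = compute_metrics(mask, (0.31, 0.31, 1.0))
        assert m.total_volume == pytest.approx(10 * 0.0961)

    def test_empty_mask_all_zero(self):
        m = compute_metrics(np.zeros((4, 4, 4), bool), (0.31, 0.31, 1.0))
        assert (m.total_volume, m.max_axial_volume, m.length) == (0.0, 0.0, 0.0)

    def test_max_axial_and_length(self):
        mask = np.zeros((8, 8, 6), bool)
        mask[0, 0:3, 2] = True   # 3 voxels on slice 2
        mask[0, 0, 3] = True     # 1 voxel on slice 3
        vox = 0.31 * 0.31 * 1.0
        m = compute_metrics(mask, (0.31, 0.31, 1.0))
        assert m.max_axial_volume == pytest.approx(3 * vox)
        assert m.length == pytest.approx(2 * 1.0)
        assert m.total_volume == pytest.approx(4 * vox)

    def test_length_counts_gap_slices(self):
        mask = np.zeros((4, 4, 10), bool)
        mask[1, 1, 2:4] = True
        mask[1, 1, 6:8] = True
        m = compute_metrics(mask, (0.31, 0.31, 1.0))
        assert m.length == pytest.approx(6 * 1.0)  # slices 2..7 inclusive


class TestSegmentIPH:
    def test_noiseless_exact_recovery_all_criteria(self, noiseless_config):
        vol, truth = generate_subject(noiseless_config)
        roi = default_scm_roi(noiseless_config)
        for ratio in (1.5, 1.75, 2.0):
            seg = segment_iph(vol, truth.plaque_mask, roi, ThresholdCriterion(ratio))
            assert seg.metrics.total_volume == truth.true_iph_volume
            np.testing.assert_array_equal(seg.mask, truth.iph_mask)

    def test_intermediate_ratio_threshold_ordering(self):
        cfg = PhantomConfig(noise=NoiseSpec(sigma=0.0),
                            iph=IPHSpec(intensity_ratio=1.6), seed=5)
        cfg.muscle.sd = 0.0
        vol, truth = generate_subject(cfg)
        roi = default_scm_roi(cfg)
        v150 = segment_iph(vol, truth.plaque_mask, roi, ThresholdCriterion(1.5))
        v175 = segment_iph(vol, truth.plaque_mask, roi, ThresholdCriterion(1.75))
        v200 = segment_iph(vol, truth.plaque_mask, roi, ThresholdCriterion(2.0))
        assert v150.metrics.total_volume == truth.true_iph_volume
        assert v175.metrics.total_volume == 0.0
        assert v200.metrics.total_volume == 0.0

    def test_matches_naive_pipeline_on_random_grids(self):
        rng = np.random.default_rng(21)
        roi_pts = [(0, 0, 0), (0, 1, 0), (1, 0, 0)]
        for _ in range(5):
            data = rng.uniform(50, 250, (12, 12, 8))
            for p in roi_pts:
                data[p] = 100.0
            plaque = rng.random((12, 12, 8)) > 0.5
            vol = _volume(data)
            seg = segment_iph(vol, plaque, ROIPointSet(points=roi_pts),
                              ThresholdCriterion(1.5))
            want = segment_iph_naive(data, plaque, 100.0, 1.5)
            np.testing.assert_array_equal(seg.mask, want)

    @given(seed=st.integers(0, 500))
    def test_threshold_mask_nesting_property(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(50, 250, (10, 10, 6))
        plaque = rng.random((10, 10, 6)) > 0.5
        ref = ReferenceIntensity(mean=100.0, point_values=(100.0,) * 3, n_points=3)
        vol = _volume(data)
        masks = [threshold_iph(vol, plaque, ref, ThresholdCriterion(r))
                 for r in (1.5, 1.75, 2.0)]
        assert np.all(masks[2] <= masks[1])
        assert np.all(masks[1] <= masks[0])

    def test_scale_invariance(self, noisy_config):
        vol, truth = generate_subject(noisy_config)
        roi = default_scm_roi(noisy_config)
        seg1 = segment_iph(vol, truth.plaque_mask, roi, ThresholdCriterion(1.5))
        scaled = Volume3D(vol.data * 3.7, spacing=vol.spacing)
        seg2 = segment_iph(scaled, truth.plaque_mask, roi, ThresholdCriterion(1.5))
        np.testing.assert_array_equal(seg1.mask, seg2.mask)
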