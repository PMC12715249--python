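"""Preprocessing stages: QC scoring, extraction, registration, intensity
normalization and coronal grid assembly."""

from dataclasses import replace

import numpy as np
import pytest

from coronal_caps.cohort import PhantomParams, render_phantom
from coronal_caps.preprocess import (SLICE_OFFSETS_MM, brain_extraction,
                                     combine_quality, construct_grid,
                                     intensity_normalization, make_template,
                                     quality_control, reference_histogram,
                                     resample_onto, segment_wm,
                                     spatial_normalization)
from coronal_caps.volume import BrainVolume
from conftest import SMALL_SHAPE, small_params


class TestQualityControl:
    def test_score_formula_hand_value(self):
        # 0.4 * (30/40) + 0.3 * 0.9 + 0.3 * 0.8 = 0.81
        score, flag = combine_quality(snr=30, motion_score=0.1, uniformity=0.8)
        assert score == pytest.approx(0.81)
        assert flag == "ACCEPT"

    def test_maximal_components_give_one(self):
        assert combine_quality(40, 0.0, 1.0) == (1.0, "ACCEPT")
        assert combine_quality(400, 0.0, 1.0) == (1.0, "ACCEPT")  # SNR capped

    @pytest.mark.parametrize("snr,motion", [(15, 0.0), (19.9, 0.0), (30, 0.31)])
    def test_rejection_gates(self, snr, motion):
        score, flag = combine_quality(snr, motion, 0.9)
        assert flag == "REJECT" and score == 0.0

    def test_low_snr_phantom_rejected(self):
        # noise sd chosen so mean(head)/sd(air) lands near 15, below the gate
        noisy = render_phantom(small_params(noise_sd=90.0 / 15), seed=3)
        report = quality_control(noisy)
        assert report.snr < 20
        assert report.flag == "REJECT" and report.quality_score == 0.0

    def test_clean_phantom_accepted(self, clean_phantom):
        report = quality_control(clean_phantom)
        assert report.flag == "ACCEPT"
        assert 0.0 < report.quality_score <= 1.0
        assert report.motion_score < 0.1

    def test_empty_volume_errors(self):
        vol = BrainVolume(np.zeros(SMALL_SHAPE), (2, 2, 2), (32, 36, 32))
        with pytest.raises(ValueError, match="empty volume"):
            quality_control(vol)


class TestBrainExtraction:
    def test_mask_matches_known_head_label(self, clean_phantom):
        brain, mask = brain_extraction(clean_phantom)
        head = clean_phantom.labels > 0
        dice = 2 * np.sum(mask & head) / (mask.sum() + head.sum())
        assert dice > 0.9

    def test_far_background_zeroed(self, clean_phantom):
        from scipy import ndimage

        brain, mask = brain_extraction(clean_phantom)
        # the soft (gradient-weighted) edge reaches a few voxels past the
        # binary mask; beyond that everything must be exactly 0
        far = ~ndimage.binary_dilation(mask, iterations=4)
        assert np.all(brain.data[far] == 0.0)

    def test_largest_component_wins(self):
        data = np.zeros((48, 48, 48))
        data[6:30, 6:30, 6:30] = 100.0   # big blob
        data[38:42, 38:42, 38:42] = 100.0  # small distractor
        vol = BrainVolume(data, (2, 2, 2), (24, 24, 24))
        _, mask = brain_extraction(vol)
        assert mask[10, 10, 10] and not mask[40, 40, 40]

    def test_idempotent_up_to_edge_softening(self, clean_phantom):
        brain, mask1 = brain_extraction(clean_phantom)
        _, mask2 = brain_extraction(brain)
        dice = 2 * np.sum(mask1 & mask2) / (mask1.sum() + mask2.sum())
        assert dice > 0.95

    def test_flat_volume_errors(self):
        vol = BrainVolume(np.zeros(SMALL_SHAPE), (2, 2, 2), (32, 36, 32))
        with pytest.raises(ValueError, match="extraction failed"):
            brain_extraction(vol)


@pytest.fixture(scope="module")
def small_template():
    return make_template(SMALL_SHAPE, (2.0, 2.0, 2.0))


class TestRegistration:
    def test_identity_registration(self, small_template):
        res = spatial_normalization(small_template, small_template)
        t = np.asarray(res.transform["translation_mm"])
        rot = np.asarray(res.transform["rotation_rad"])
        assert np.all(np.abs(t) < 1.0)          # < 0.5 voxel at 2 mm
        assert np.all(np.abs(rot) < np.deg2rad(1.0))
        assert res.registered.shape == small_template.shape

    def test_known_translation_recovered(self, small_template):
        # moving = template content shifted by (5, -3, 2) voxels = (10, -6, 4) mm
        p_inv = np.zeros(12)
        p_inv[:3] = [-10, 6, -4]
        moving = replace(small_template,
                         data=resample_onto(small_template, small_template, p_inv),
                         labels=None)
        res = spatial_normalization(moving, small_template)
        got = np.asarray(res.transform["translation_mm"])
        assert np.all(np.abs(got - [10, -6, 4]) < 1.0)  # 0.5 voxel

    def test_known_scale_recovered(self, small_template):
        p_inv = np.zeros(12)
        p_inv[6:9] = -np.log(1.1)
        moving = replace(small_template,
                         data=resample_onto(small_template, small_template, p_inv),
                         labels=None)
        res = spatial_normalization(moving, small_template)
        assert np.allclose(res.transform["scale"], 1.1, rtol=0.02)

    def test_cost_not_worse_than_initialization(self, small_template):
        res = spatial_normalization(small_template, small_template)
        assert res.cost_value <= 0.05


class TestIntensityNormalization:
    def test_wm_tier_zscores_to_zero(self, noiseless_phantom):
        brain, mask = brain_extraction(noiseless_phantom)
        wm_mean, _ = segment_wm(brain.data, mask)
        # the WM tier of the piecewise-constant phantom is its own mean
        assert wm_mean == pytest.approx(120.0, abs=2.0)

    def test_output_range_8bit(self, clean_phantom):
        brain, mask = brain_extraction(clean_phantom)
        out = intensity_normalization(brain, mask)
        assert out.data.min() >= 0.0 and out.data.max() <= 255.0

    def test_matching_own_distribution_is_identity(self, clean_phantom):
        brain, mask = brain_extraction(clean_phantom)
        plain = intensity_normalization(brain, mask, reference=None)
        wm_mean, wm_sd = segment_wm(brain.data, mask)
        ref = reference_histogram((brain.data[mask] - wm_mean) / wm_sd)
        matched = intensity_normalization(brain, mask, reference=ref)
        # quantization/interpolation aside, self-matching changes little
        diff = np.abs(plain.data[mask] - matched.data[mask])
        assert np.median(diff) < 3.0

    def test_empty_mask_errors(self, clean_phantom):
        with pytest.raises(ValueError, match="empty"):
            intensity_normalization(clean_phantom, np.zeros(SMALL_SHAPE, bool))


class TestGridConstruction:
    def test_shape_and_dtype_exact(self, clean_phantom):
        grid = construct_grid(clean_phantom)
        assert grid.pixels.shape == (512, 512)
        assert grid.pixels.dtype == np.uint8
        assert grid.slice_positions_mm == SLICE_OFFSETS_MM

    def test_offsets_span_18mm(self):
        assert max(SLICE_OFFSETS_MM) - min(SLICE_OFFSETS_MM) == 18

    def test_constant_volume_gives_constant_grid(self):
        vol = BrainVolume(np.full(SMALL_SHAPE, 37.0), (2, 2, 2), (32, 36, 32))
        grid = construct_grid(vol)
        assert np.unique(grid.pixels).tolist() == [37]

    def test_bright_origin_slice_lands_in_top_row_block_5(self):
        data = np.zeros(SMALL_SHAPE)
        data[:, 36, :] = 255.0  # the y = 0 mm plane (5th of the 10 offsets)
        grid = construct_grid(BrainVolume(data, (2, 2, 2), (32, 36, 32)))
        cols = grid.pixels.sum(axis=0).astype(float)
        rows = grid.pixels.sum(axis=1).astype(float)
        col_centroid = (cols * np.arange(512)).sum() / cols.sum()
        row_centroid = (rows * np.arange(512)).sum() / rows.sum()
        assert 408 <= col_centroid <= 512   # 5th block of 5, each ~102 wide
        assert row_centroid < 256           # top (posterior) row

    def test_left_right_orientation_preserved(self):
        # marker on one anatomical side must stay on the same horizontal side
        # of every slice block
        data = np.zeros(SMALL_SHAPE)
        data[4:10, :, :] = 200.0  # low-x slab through all coronal planes
        grid = construct_grid(BrainVolume(data, (2, 2, 2), (32, 36, 32)))
        for block in range(5):
            band = grid.pixels[:256, block * 102:(block + 1) * 102].astype(float)
            left, right = band[:, :51].sum(), band[:, 51:].sum()
            assert left > right

    def test_out_of_volume_offset_named_in_error(self):
        vol = BrainVolume(np.zeros((16, 16, 16)) + 1.0, (2, 2, 2), (8, 14, 8))
        with pytest.raises(ValueError, match=r"offset 4 mm"):
            construct_grid(vol)  # 14 + 4/2 = index 16, first offset to fall out

    def test_pipeline_composition_deterministic(self, clean_phantom):
        def run():
            brain, mask = brain_extraction(clean_phantom)
            norm = intensity_normalization(brain, mask)
            return construct_grid(norm).pixels

        assert np.array_equal(run(), run())
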