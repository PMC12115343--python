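"""Volume-series estimation: pixel-wise and spatial-average methods."""

import numpy as np
import pytest

from depthresp import (CameraIntrinsics, DepthSequence, EmptyROIError,
                       PhantomConfig, area_map, compute_volume_baseline,
                       compute_volume_series, generate_sequence, invert_and_zero,
                       rasterize_obb, fixed_roi)
from depthresp.phantom import _surface_depth, dome_height_field

from conftest import small_phantom


def _flat_sequence(depths_mm, intr=None, fps=30.0):
    intr = intr or CameraIntrinsics.from_fov(32, 32)
    frames = np.stack([np.full((intr.height, intr.width), d) for d in depths_mm])
    return DepthSequence.from_mm(frames, fps=fps, intrinsics=intr), intr


def _footprint_mask(cfg):
    intr = cfg.intrinsics
    ref = _surface_depth(cfg, 0.0)
    uu, vv = np.meshgrid(np.arange(intr.width, dtype=float),
                         np.arange(intr.height, dtype=float))
    x = (uu - intr.cx) * ref / intr.fx
    y = (vv - intr.cy) * ref / intr.fy
    return dome_height_field(x, y, cfg) > 0, ref


def _estimated_vt(cfg):
    """Peak-to-trough of the pixel-wise series over the analytic footprint."""
    seq, _ = generate_sequence(cfg)
    mask, ref = _footprint_mask(cfg)
    areas, eff = area_map(cfg.intrinsics, ref, mask)
    v = invert_and_zero(compute_volume_series(seq, areas, eff)).volume
    return v.max() - v.min()


class TestPixelwise:
    def test_static_scene_constant_then_zero(self):
        seq, intr = _flat_sequence([1000.0] * 20)
        mask = np.ones((32, 32), dtype=bool)
        areas, eff = area_map(intr, seq.depth_mm(0), mask)
        raw = compute_volume_series(seq, areas, eff)
        assert np.ptp(raw.volume) == 0.0
        processed = invert_and_zero(raw)
        np.testing.assert_array_equal(processed.volume, 0.0)

    def test_single_pixel_unit_conversion(self):
        intr = CameraIntrinsics(fx=500, fy=500, cx=16, cy=16, width=32, height=32)
        seq, _ = _flat_sequence([1000.0], intr=intr)
        mask = np.zeros((32, 32), dtype=bool)
        mask[10, 10] = True
        areas, eff = area_map(intr, seq.depth_mm(0), mask)
        raw = compute_volume_series(seq, areas, eff)
        # 1000 mm depth x 4 mm^2 = 4000 mm^3 = 4 mL
        assert raw.volume[0] == pytest.approx(4.0, rel=1e-9)

    def test_phantom_end_inspiration_drop_equals_vt(self):
        cfg = small_phantom(noise_sigma=0.0, duration=6.0)
        seq, truth = generate_sequence(cfg)
        mask, ref = _footprint_mask(cfg)
        areas, eff = area_map(cfg.intrinsics, ref, mask)
        raw = compute_volume_series(seq, areas, eff)
        k = int(np.argmax(truth.true_volume))
        drop = raw.volume[k] - raw.volume[0]
        assert drop == pytest.approx(-cfg.vt_true, rel=0.01)

    def test_empty_mask_raises(self):
        seq, intr = _flat_sequence([1000.0] * 3)
        with pytest.raises(EmptyROIError):
            compute_volume_series(seq, np.zeros((32, 32)),
                                  np.zeros((32, 32), dtype=bool))

    def test_temporal_hold_and_quality_warning(self):
        cfg = small_phantom(noise_sigma=0.0, duration=3.0)
        seq, _ = generate_sequence(cfg)
        mask, ref = _footprint_mask(cfg)
        areas, eff = area_map(cfg.intrinsics, ref, mask)
        clean = compute_volume_series(seq, areas, eff)
        # knock out 30% of ROI pixels in the second half of the frames
        data = seq.data.copy()
        idx = np.flatnonzero(eff.ravel())
        dead = idx[: int(0.3 * len(idx))]
        flat = data.reshape(data.shape[0], -1)
        flat[data.shape[0] // 2:, dead] = 0
        broken = DepthSequence(data=data, fps=seq.fps, intrinsics=seq.intrinsics)
        held = compute_volume_series(broken, areas, eff, reference_frame=ref)
        assert held.meta["held_fraction_max"] == pytest.approx(0.3, abs=0.01)
        assert held.meta["quality_warnings"]
        # held values freeze at the last valid depth: series stays finite & close
        assert np.all(np.isfinite(held.volume))
        assert np.abs(held.volume - clean.volume).max() < 0.35 * cfg.vt_true


class TestInvertAndZero:
    def test_constant_becomes_zero(self):
        seq, intr = _flat_sequence([900.0] * 5)
        series = compute_volume_series(
            seq, *area_map(intr, seq.depth_mm(0), np.ones((32, 32), bool)))
        out = invert_and_zero(series)
        np.testing.assert_allclose(out.volume, 0.0, atol=1e-12)
        assert out.volume[0] == 0.0

    def test_sign_flip(self):
        seq, intr = _flat_sequence([1000.0, 999.0, 998.0])  # moving toward camera
        series = compute_volume_series(
            seq, *area_map(intr, seq.depth_mm(0), np.ones((32, 32), bool)))
        out = invert_and_zero(series)
        assert out.volume[0] == 0.0
        assert np.all(np.diff(out.volume) > 0)

    def test_double_inversion_restores_zeroed_shape(self):
        seq, intr = _flat_sequence([1000.0, 999.5, 1000.2, 999.8])
        series = compute_volume_series(
            seq, *area_map(intr, seq.depth_mm(0), np.ones((32, 32), bool)))
        twice = invert_and_zero(invert_and_zero(series))
        np.testing.assert_allclose(twice.volume, series.volume - series.volume[0],
                                   atol=1e-9)


class TestBaselineMethod:
    def test_translating_plane_hand_computation(self):
        # fronto-parallel 100x100 px ROI at 1000 mm, fx=fy=500 -> S = 40,000 mm^2;
        # plane moves 1 mm toward the camera -> V = +40 mL after inversion
        intr = CameraIntrinsics(fx=500, fy=500, cx=60, cy=60, width=120, height=120)
        frames = np.stack([np.full((120, 120), 1000.0), np.full((120, 120), 999.0)])
        seq = DepthSequence.from_mm(frames, fps=30.0, intrinsics=intr)
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 10:110] = True
        out = compute_volume_baseline(seq, mask, intr)
        assert out.volume[0] == 0.0
        assert out.volume[1] == pytest.approx(40.0, rel=1e-6)

    def test_static_scene_all_zero(self):
        seq, intr = _flat_sequence([1000.0] * 10)
        out = compute_volume_baseline(seq, np.ones((32, 32), bool), intr)
        np.testing.assert_allclose(out.volume, 0.0, atol=1e-9)

    def test_close_to_pixelwise_on_near_frontoparallel_dome(self):
        cfg = small_phantom(noise_sigma=0.0, duration=6.0)
        seq, _ = generate_sequence(cfg)
        mask, ref = _footprint_mask(cfg)
        areas, eff = area_map(cfg.intrinsics, ref, mask)
        pix = invert_and_zero(compute_volume_series(seq, areas, eff))
        base = compute_volume_baseline(seq, mask, cfg.intrinsics, reference_frame=ref)
        vt_pix = np.ptp(pix.volume)
        vt_base = np.ptp(base.volume)
        assert vt_base == pytest.approx(vt_pix, rel=0.10)


class TestVtInvariances:
    def test_linearity_in_amplitude(self):
        vt1 = _estimated_vt(small_phantom(noise_sigma=0.0, duration=6.0, vt_true=200.0))
        vt2 = _estimated_vt(small_phantom(noise_sigma=0.0, duration=6.0, vt_true=400.0))
        assert vt2 / vt1 == pytest.approx(2.0, rel=0.01)

    @pytest.mark.parametrize("distance", [700.0, 1500.0])
    def test_distance_invariance(self, distance):
        ref_vt = _estimated_vt(small_phantom(noise_sigma=0.0, duration=6.0,
                                             bed_distance=1100.0))
        vt = _estimated_vt(small_phantom(noise_sigma=0.0, duration=6.0,
                                         bed_distance=distance))
        assert vt == pytest.approx(ref_vt, rel=0.02)

    @pytest.mark.parametrize("shift", [(-100.0, 0.0), (100.0, 0.0)])
    def test_off_center_invariance(self, shift):
        ref_vt = _estimated_vt(small_phantom(noise_sigma=0.0, duration=6.0))
        vt = _estimated_vt(small_phantom(noise_sigma=0.0, duration=6.0,
                                         torso_center=shift))
        assert vt == pytest.approx(ref_vt, rel=0.02)

    def test_pixelwise_beats_baseline_on_tilted_dome(self):
        # Tilted bed, dome on the near (small-pixel-area) side, ROI including
        # plenty of bed: the spatial-average method weights the dome's depth
        # change by the ROI-average pixel area instead of the local one.
        cfg = small_phantom(noise_sigma=0.0, duration=6.0, plane_tilt_deg=25.0,
                            torso_center=(0.0, -100.0))
        seq, _ = generate_sequence(cfg)
        mask = rasterize_obb(fixed_roi("79.5,71.5,140,120,0"), 160, 144)
        ref = _surface_depth(cfg, 0.0)
        areas, eff = area_map(cfg.intrinsics, ref, mask)
        pix = invert_and_zero(compute_volume_series(seq, areas, eff))
        base = compute_volume_baseline(seq, mask, cfg.intrinsics, reference_frame=ref)
        err_pix = abs(np.ptp(pix.volume) - cfg.vt_true)
        err_base = abs(np.ptp(base.volume) - cfg.vt_true)
        assert err_pix <= err_base
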