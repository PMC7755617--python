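"""Volumetry, ratios, long-axis frames, and P-A profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hippoquant as hq
from hippoquant.morphometry_profiles import (
    DegenerateMaskError,
    compute_global_metrics,
    global_qt2,
    long_axis_frame,
    lr_ratio_pct,
    mask_volume_mm3,
    profile,
)
from hippoquant.phantom import Grid, HippocampusSpec, make_hippocampus_mask


def _mask_from_array(data, spacing=(1.0, 1.0, 1.0), side="left"):
    return hq.LabelMask(data=data.astype(np.uint8), affine=np.diag([*spacing, 1.0]), side=side)


class TestVolume:
    def test_isotropic_arithmetic(self):
        data = np.zeros((20, 20, 20))
        data.flat[:1000] = 1
        assert mask_volume_mm3(_mask_from_array(data)) == 1000.0

    def test_anisotropic_arithmetic(self):
        data = np.zeros((40, 40, 4))
        data.flat[:1000] = 1
        m = _mask_from_array(data, spacing=(0.43, 0.43, 4.0))
        assert mask_volume_mm3(m) == pytest.approx(739.6, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_volume_mm3(_mask_from_array(np.zeros((4, 4, 4))))


class TestGlobalQt2:
    def _map(self, values, valid=None):
        t2 = np.asarray(values, dtype=float)
        valid = np.ones_like(t2, dtype=bool) if valid is None else valid
        vol = hq.Volume3D(data=t2, affine=np.eye(4))
        s0 = hq.Volume3D(data=np.ones_like(t2), affine=np.eye(4))
        return hq.T2Map(t2=vol, s0=s0, valid=valid, clamped=np.zeros_like(valid))

    def test_mean_and_median_on_split_values(self):
        vals = np.zeros((4, 4, 4))
        vals[:2] = 90.0
        vals[2:] = 110.0
        m = _mask_from_array(np.ones((4, 4, 4)))
        t2map = self._map(vals)
        assert global_qt2(m, t2map, "mean") == pytest.approx(100.0)
        assert global_qt2(m, t2map, "median") == pytest.approx(100.0)

    def test_invalid_voxels_excluded(self):
        vals = np.full((4, 4, 4), 100.0)
        vals[0, 0, 0] = 5000.0
        valid = np.ones((4, 4, 4), dtype=bool)
        valid[0, 0, 0] = False
        m = _mask_from_array(np.ones((4, 4, 4)))
        assert global_qt2(m, self._map(vals, valid)) == pytest.approx(100.0)

    def test_no_valid_voxels_rejected(self):
        m = _mask_from_array(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            global_qt2(m, self._map(np.ones((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool)))


class TestRatio:
    def test_examples(self):
        assert lr_ratio_pct(2400.0, 3000.0) == pytest.approx(80.0)
        assert lr_ratio_pct(7.0, 7.0) == 100.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            lr_ratio_pct(1.0, 0.0)

    @given(a=st.floats(1.0, 1e4), b=st.floats(1.0, 1e4))
    def test_antisymmetry_identity(self, a, b):
        assert lr_ratio_pct(a, b) * lr_ratio_pct(b, a) == pytest.approx(1e4, rel=1e-9)


def _straight_tube_mask(grid_shape=(32, 64, 32)):
    cl = np.array([[0.0, -20.0, 0.0], [0.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
    spec = HippocampusSpec(side="right", centerline=cl, base_radius=5.0, taper=1.0)
    return make_hippocampus_mask(spec, Grid.centered(grid_shape, (1.0, 1.0, 1.0))), spec


class TestLongAxisFrame:
    def test_straight_tube_direction_is_anterior(self):
        mask, _ = _straight_tube_mask()
        frame = long_axis_frame(mask)
        np.testing.assert_allclose(frame.direction, [0.0, 1.0, 0.0], atol=1e-6)

    def test_index_flip_does_not_flip_world_direction(self):
        mask, _ = _straight_tube_mask()
        flipped = hq.LabelMask(
            data=mask.data[:, ::-1, :].copy(), affine=mask.affine.copy(), side="right"
        )
        d0 = long_axis_frame(mask).direction
        d1 = long_axis_frame(flipped).direction
        # sign convention is anchored in world anterior, not voxel order
        assert d0 @ d1 > 0.999

    def test_curved_tube_within_10_degrees_of_chord(self):
        mask = make_hippocampus_mask(HippocampusSpec(side="right"), hq.phantom.default_grid())
        cl = hq.phantom.default_centerline("right")
        chord = cl[-1] - cl[0]
        chord = chord / np.linalg.norm(chord)
        d = long_axis_frame(mask).direction
        angle = np.degrees(np.arccos(min(1.0, abs(d @ chord))))
        assert angle <= 10.0

    def test_too_few_voxels_rejected(self):
        data = np.zeros((8, 8, 8))
        data[0, :3, 0] = 1
        with pytest.raises(DegenerateMaskError):
            long_axis_frame(_mask_from_array(data))

    def test_degenerate_sphere_rejected(self):
        ii, jj, kk = np.meshgrid(*(np.arange(20),) * 3, indexing="ij")
        ball = ((ii - 10) ** 2 + (jj - 10) ** 2 + (kk - 10) ** 2) <= 49
        with pytest.raises(DegenerateMaskError):
            long_axis_frame(_mask_from_array(ball))

    def test_frame_stable_under_boundary_perturbation(self):
        from scipy import ndimage

        mask, _ = _straight_tube_mask()
        boundary = mask.data.astype(bool) & ~ndimage.binary_erosion(mask.data.astype(bool))
        b_idx = np.argwhere(boundary)
        rng = np.random.default_rng(4)
        n_remove = max(1, int(0.01 * mask.n_voxels))
        drop = b_idx[rng.choice(len(b_idx), n_remove, replace=False)]
        perturbed = mask.data.copy()
        perturbed[drop[:, 0], drop[:, 1], drop[:, 2]] = 0
        d0 = long_axis_frame(mask).direction
        d1 = long_axis_frame(_mask_from_array(perturbed, side="right")).direction
        assert np.degrees(np.arccos(min(1.0, abs(d0 @ d1)))) <= 2.0


class TestProfile:
    def test_cylinder_interior_bin_area(self):
        mask, _ = _straight_tube_mask()
        frame = long_axis_frame(mask)
        p = profile(mask, None, frame, n_bins=20)
        interior = p.area_mm2[5:15]
        np.testing.assert_allclose(interior, np.pi * 25.0, rtol=0.10)

    def test_bin_volumes_conserve_mask_volume_exactly(self, unilateral_subject, unilateral_t2map):
        for mask in (unilateral_subject.mask_left, unilateral_subject.mask_right):
            frame = long_axis_frame(mask)
            p = profile(mask, unilateral_t2map, frame)
            assert p.bin_volume_mm3.sum() == mask_volume_mm3(mask)

    def test_focal_bump_localised(self):
        acq = hq.AcquisitionSpec(noise_sigma=10.0, seed=17)
        sub = hq.make_phantom_subject(
            HippocampusSpec(side="left", t2_elevation=1.15, focal_center=0.5),
            HippocampusSpec(side="right"),
            acq,
        )
        t2map = hq.compute_t2_map(sub.echo1, sub.echo2, roi=sub.mask_left)
        frame = long_axis_frame(sub.mask_left)
        p = profile(sub.mask_left, t2map, frame, n_bins=20)
        peak = int(np.nanargmax(p.qt2_ms))
        # 0.5 lies on the closed boundary between the two central bins
        assert peak in (9, 10)

    def test_n_bins_validation(self, noise_free_subject, noise_free_t2map):
        frame = long_axis_frame(noise_free_subject.mask_left)
        with pytest.raises(ValueError):
            profile(noise_free_subject.mask_left, noise_free_t2map, frame, n_bins=1)

    def test_positions_increase_posterior_to_anterior(self, noise_free_subject, noise_free_t2map):
        frame = long_axis_frame(noise_free_subject.mask_left)
        p = profile(noise_free_subject.mask_left, noise_free_t2map, frame)
        assert np.all(np.diff(p.positions) > 0)


class TestGlobalMetrics:
    def test_symmetric_phantom_ratios_100(self, noise_free_subject, noise_free_t2map):
        m = compute_global_metrics(
            noise_free_subject.mask_left, noise_free_subject.mask_right, noise_free_t2map
        )
        assert m.lr_vol_ratio_pct == pytest.approx(100.0)
        assert m.lr_qt2_ratio_pct == pytest.approx(100.0)

    def test_unilateral_phantom_recovers_truth(self, unilateral_subject, unilateral_t2map):
        m = compute_global_metrics(
            unilateral_subject.mask_left, unilateral_subject.mask_right, unilateral_t2map
        )
        assert m.lr_vol_ratio_pct == pytest.approx(70.0, abs=3.0)
        # left T2 elevated 10% -> L:R qT2 ratio ~110%
        assert m.lr_qt2_ratio_pct == pytest.approx(110.0, abs=1.5)
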