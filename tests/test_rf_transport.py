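"""Receptive-field transport: point transport, masks, lag stacking, fish-eye."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxel2pixel.rf_transport import (
    Canvas, RFCenterTable, VoxelSeries, build_point_transport, apply_transport,
    make_perturbation_mask, stack_lags, fisheye_warp, zscore, round_half_down,
)


def brute_force_transport(table, canvas, responses):
    """Direct per-pixel mean over voxels whose center rounds to the pixel."""
    img = np.zeros((canvas.height, canvas.width))
    cnt = np.zeros_like(img)
    for x, y, r in zip(table.x, table.y, responses):
        # in-canvas coordinates in [W - 0.5, W) round to the edge pixel
        px = min(round_half_down(x), canvas.width - 1)
        py = min(round_half_down(y), canvas.height - 1)
        img[py, px] += r
        cnt[py, px] += 1
    return np.where(cnt > 0, img / np.maximum(cnt, 1), 0.0), cnt


class TestPointTransport:
    def test_two_voxels_same_pixel_average(self, small_canvas):
        table = RFCenterTable("V1", [4.2, 3.9], [6.8, 7.3])  # both round to (4, 7)
        op = build_point_transport(table, small_canvas)
        img = apply_transport(op, np.array([0.2, 0.6]))
        assert img[7, 4] == pytest.approx(0.4)
        assert op.coverage_count[7, 4] == 2
        assert op.coverage_count.sum() == 2

    def test_zero_responses_zero_image(self, rf_table, small_canvas):
        op = build_point_transport(rf_table, small_canvas)
        assert np.all(apply_transport(op, np.zeros(rf_table.n_voxels)) == 0)

    def test_matches_brute_force_oracle(self, small_canvas):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 20))
            table = RFCenterTable("V1", rng.uniform(0, 8, n), rng.uniform(0, 8, n))
            resp = rng.normal(size=n)
            op = build_point_transport(table, small_canvas)
            img = apply_transport(op, resp)
            expected, cnt = brute_force_transport(table, small_canvas, resp)
            np.testing.assert_allclose(img, expected, atol=1e-12)
            np.testing.assert_array_equal(op.coverage_count, cnt)

    def test_conservation(self, rf_table, small_canvas, rng):
        """Sum over pixels of value * M equals the sum of voxel responses."""
        op = build_point_transport(rf_table, small_canvas)
        resp = rng.normal(size=rf_table.n_voxels)
        img = apply_transport(op, resp)
        assert (img * op.coverage_count).sum() == pytest.approx(resp.sum())

    def test_permutation_equivariance(self, rf_table, small_canvas, rng):
        resp = rng.normal(size=rf_table.n_voxels)
        perm = rng.permutation(rf_table.n_voxels)
        permuted = RFCenterTable("V1", rf_table.x[perm], rf_table.y[perm])
        img1 = apply_transport(build_point_transport(rf_table, small_canvas), resp)
        img2 = apply_transport(build_point_transport(permuted, small_canvas), resp[perm])
        np.testing.assert_allclose(img1, img2, atol=1e-12)

    def test_uniform_responses_give_indicator(self, rf_table, small_canvas):
        op = build_point_transport(rf_table, small_canvas)
        img = apply_transport(op, np.ones(rf_table.n_voxels))
        covered = op.coverage_count > 0
        assert np.allclose(img[covered], 1.0) and np.all(img[~covered] == 0)

    def test_linearity_in_responses(self, rf_table, small_canvas, rng):
        op = build_point_transport(rf_table, small_canvas)
        resp = rng.normal(size=rf_table.n_voxels)
        np.testing.assert_allclose(apply_transport(op, 3.5 * resp),
                                   3.5 * apply_transport(op, resp), atol=1e-12)

    def test_errors(self, small_canvas):
        with pytest.raises(ValueError, match="no voxels"):
            RFCenterTable("V1", [], [])
        with pytest.raises(ValueError, match="NaN"):
            RFCenterTable("V1", [np.nan], [1.0])
        table = RFCenterTable("V1", [2.0], [2.0])
        op = build_point_transport(table, small_canvas)
        with pytest.raises(ValueError, match="expected 1 responses"):
            apply_transport(op, np.ones(3))


class TestPerturbationMask:
    def test_mask_times_ones_equals_fixed_transport(self, rf_table, small_canvas, rng):
        op = build_point_transport(rf_table, small_canvas)
        mask = make_perturbation_mask(rf_table, small_canvas)
        w = mask.to_sparse().multiply(mask.normalizer)
        np.testing.assert_allclose(w.toarray(), op.weights.toarray(), atol=1e-15)

    def test_each_voxel_maps_to_one_pixel(self, rf_table, small_canvas):
        mask = make_perturbation_mask(rf_table, small_canvas)
        col_sums = np.asarray(mask.to_sparse().sum(axis=0)).ravel()
        np.testing.assert_array_equal(col_sums, 1)

    def test_corner_voxel_single_entry(self, small_canvas):
        mask = make_perturbation_mask(RFCenterTable("V1", [0.0], [0.0]), small_canvas)
        assert mask.pixel_index.tolist() == [0]
        assert mask.normalizer.tolist() == [1.0]


class TestStackLags:
    def _series(self, n_t, n_v, rng):
        return VoxelSeries("V1", rng.normal(size=(n_t, n_v)))

    def test_single_lag_picks_delayed_volume(self, rf_table, small_canvas, rng):
        series = self._series(12, rf_table.n_voxels, rng)
        op = build_point_transport(rf_table, small_canvas)
        imgs, kept = stack_lags(series, op, 1, lagset=(5,))
        assert kept == [0]
        np.testing.assert_allclose(imgs[0, 0],
                                   apply_transport(op, series.values[5]), atol=1e-12)

    def test_five_lags_three_rois_fifteen_channels(self, small_canvas, rng):
        from voxel2pixel.rf_transport import build_rfs_dataset
        tables = {r: RFCenterTable(r, rng.uniform(0, 8, 6), rng.uniform(0, 8, 6))
                  for r in ("V1", "V2", "V3")}
        ops = {r: build_point_transport(t, small_canvas) for r, t in tables.items()}
        series = {r: self._series(20, 6, rng) for r in tables}
        x, kept, roi_order = build_rfs_dataset(series, ops, 10, (3, 4, 5, 6, 7),
                                               ("V1", "V2", "V3"))
        assert x.shape[1] == 15
        assert roi_order == ("V1", "V2", "V3")

    def test_constant_series_identical_channels(self, rf_table, small_canvas):
        vals = np.tile(np.arange(rf_table.n_voxels, dtype=float), (15, 1))
        series = VoxelSeries("V1", vals)
        op = build_point_transport(rf_table, small_canvas)
        imgs, _ = stack_lags(series, op, 5, lagset=(3, 4, 5, 6, 7))
        for j in range(1, 5):
            np.testing.assert_array_equal(imgs[:, j], imgs[:, 0])

    def test_overrunning_stimuli_excluded(self, rf_table, small_canvas, rng):
        series = self._series(10, rf_table.n_voxels, rng)
        op = build_point_transport(rf_table, small_canvas)
        imgs, kept = stack_lags(series, op, 10, lagset=(3, 4, 5))
        assert kept == list(range(5))  # i + 5 < 10
        assert len(imgs) == 5

    def test_empty_lagset_rejected(self, rf_table, small_canvas, rng):
        op = build_point_transport(rf_table, small_canvas)
        with pytest.raises(ValueError, match="lagset"):
            stack_lags(self._series(10, rf_table.n_voxels, rng), op, 2, lagset=())


class TestFisheye:
    def test_strength_zero_is_identity(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        out = fisheye_warp(img, 0.0)
        assert np.abs(out[2:-2, 2:-2] - img[2:-2, 2:-2]).max() < 1e-6

    def test_center_fixed_point(self, rng):
        img = rng.uniform(size=(17, 17, 3))  # odd size: center on a pixel
        for s in (0.2, 0.5, 1.0):
            out = fisheye_warp(img, s)
            np.testing.assert_allclose(out[8, 8], img[8, 8], atol=1e-9)

    def test_disc_grows_per_analytic_radius_map(self):
        h = 96
        yy, xx = np.mgrid[0:h, 0:h].astype(float)
        c = (h - 1) / 2
        r_src_disc = 12.0
        img = ((xx - c) ** 2 + (yy - c) ** 2 <= r_src_disc**2).astype(float)[..., None]
        img = np.repeat(img, 3, axis=2)
        strength = 0.5
        out = fisheye_warp(img, strength)
        area = (out[..., 0] > 0.5).sum()
        r_measured = np.sqrt(area / np.pi)
        radius = h / 2.0
        r_expected = radius * (r_src_disc / radius) ** (1 / (1 + strength))
        assert abs(r_measured - r_expected) / r_expected < 0.1

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            fisheye_warp(np.zeros((8, 10, 3)), 0.5)


class TestZscore:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(2, 30), st.integers(1, 5), st.integers(0, 10_000))
    def test_zscored_moments(self, t, v, seed):
        vals = np.random.default_rng(seed).normal(2.0, 5.0, size=(t, v))
        z = zscore(vals)
        assert np.abs(z.mean(axis=0)).max() < 1e-6
        assert np.abs(z.std(axis=0) - 1).max() < 1e-6

    def test_constant_voxel_maps_to_zero(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0)])
        z = zscore(vals)
        assert np.all(z[:, 0] == 0)
        assert z[:, 1].std() == pytest.approx(1.0)
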