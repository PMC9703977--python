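"""Readers/writers, NIfTI extraction, resampling, splits, manifests, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from voxel2pixel.cli import main
from voxel2pixel.dataio import (
    RunConfig, load_rf_centers, save_rf_centers, extract_voxel_series,
    save_rfs_stacks, load_rfs_stacks, save_voxel_series, load_voxel_series,
    save_frames_png, load_video_frames, resample_video, split_by_fraction,
    write_manifest, read_manifest,
)
from voxel2pixel.rf_transport import Canvas, RFCenterTable
from voxel2pixel.synthetic_data import make_toy_video


class TestRFCenterCSV:
    def test_roundtrip(self, tmp_path, rng):
        canvas = Canvas(16, 16)
        tables = {r: RFCenterTable(r, rng.uniform(0, 16, 5), rng.uniform(0, 16, 5))
                  for r in ("V1", "V2")}
        save_rf_centers(tmp_path / "rf.csv", tables)
        loaded = load_rf_centers(tmp_path / "rf.csv", canvas)
        for r in tables:
            np.testing.assert_allclose(loaded[r].x, tables[r].x)
            np.testing.assert_allclose(loaded[r].y, tables[r].y)

    def test_out_of_canvas_voxels_dropped_and_reindexed(self, tmp_path):
        (tmp_path / "rf.csv").write_text(
            "roi,voxel,x,y\nV1,0,2.0,3.0\nV1,1,99.0,3.0\nV1,2,5.0,5.0\n")
        loaded = load_rf_centers(tmp_path / "rf.csv", Canvas(16, 16))
        assert loaded["V1"].n_voxels == 2
        np.testing.assert_allclose(loaded["V1"].x, [2.0, 5.0])

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "rf.csv").write_text("roi,x,y\nV1,2.0,3.0\n")
        with pytest.raises(ValueError, match="columns"):
            load_rf_centers(tmp_path / "rf.csv", Canvas(16, 16))


class TestNifti:
    def test_extraction_matches_mask_scan_order(self, tmp_path, rng):
        nib = pytest.importorskip("nibabel")
        bold = rng.normal(size=(4, 5, 3, 20))
        mask = np.zeros((4, 5, 3), dtype=np.uint8)
        mask[1, 2, 0] = 1
        mask[3, 0, 2] = 1
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(bold, affine), tmp_path / "bold.nii.gz")
        nib.save(nib.Nifti1Image(mask, affine), tmp_path / "v1.nii.gz")
        series = extract_voxel_series(tmp_path / "bold.nii.gz",
                                      {"V1": tmp_path / "v1.nii.gz"},
                                      standardize=False)
        assert series["V1"].values.shape == (20, 2)
        np.testing.assert_allclose(series["V1"].values[:, 0], bold[1, 2, 0])
        np.testing.assert_allclose(series["V1"].values[:, 1], bold[3, 0, 2])


class TestHDF5:
    def test_rfs_roundtrip(self, tmp_path, rng):
        stacks = rng.normal(size=(4, 6, 16, 16))
        save_rfs_stacks(tmp_path / "rfs.h5", stacks, ("V1", "V2"), (3, 4, 5),
                        Canvas(16, 16), [0, 1, 2, 3])
        loaded, idx, attrs = load_rfs_stacks(tmp_path / "rfs.h5")
        np.testing.assert_array_equal(loaded, stacks)
        assert attrs["roi_order"] == ("V1", "V2")
        assert attrs["lagset"] == (3, 4, 5)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])

    def test_voxel_series_roundtrip(self, tmp_path, rng):
        from voxel2pixel.rf_transport import VoxelSeries
        series = {"V1": VoxelSeries("V1", rng.normal(size=(10, 4)))}
        save_voxel_series(tmp_path / "r.h5", series)
        loaded = load_voxel_series(tmp_path / "r.h5")
        np.testing.assert_array_equal(loaded["V1"].values, series["V1"].values)
        assert loaded["V1"].tr_seconds == 0.7


class TestVideo:
    def test_png_sequence_roundtrip(self, tmp_path):
        video = make_toy_video(5, Canvas(16, 16), seed=1)
        save_frames_png(tmp_path / "v", video)
        loaded, fps = load_video_frames(tmp_path / "v")
        assert fps is None
        assert loaded.shape == video.shape
        assert np.abs(loaded - video).max() < 1 / 255 + 1e-9  # 8-bit quantization

    def test_resample_rate_is_one_over_tr(self):
        # 25 fps, 7 s -> floor(7 / 0.7) = 10 frames at 1.42857142857 fps
        frames = np.zeros((175, 16, 16, 3))
        out = resample_video(frames, Canvas(16, 16), tr_seconds=0.7, source_fps=25)
        assert len(out) == 10

    def test_nearest_frame_timestamps(self):
        # encode the source frame index in the frame values
        n_src, fps, tr = 50, 25.0, 0.7
        frames = np.arange(n_src, dtype=float)[:, None, None, None] * np.ones((1, 8, 8, 3))
        frames = frames / n_src
        out = resample_video(frames, Canvas(8, 8), tr_seconds=tr, source_fps=fps)
        got = np.round(out[:, 0, 0, 0] * n_src).astype(int)
        expected = [int(round(k * tr * fps)) for k in range(len(out))]
        assert got.tolist() == expected

    def test_spatial_resize(self):
        frames = np.random.default_rng(0).uniform(size=(10, 24, 24, 3))
        out = resample_video(frames, Canvas(16, 16), tr_seconds=0.7, source_fps=5)
        assert out.shape[1:] == (16, 16, 3)

    def test_unreadable_path_rejected(self, tmp_path):
        (tmp_path / "x.webm").write_bytes(b"not a video")
        with pytest.raises(ValueError, match="cannot decode|no PNG"):
            load_video_frames(tmp_path / "x.webm")


class TestSplit:
    @pytest.mark.parametrize("fraction,expected", [
        (4 / 5, 95_200), (3 / 5, 71_400), (1 / 5, 23_800), (2 / 5, 47_600),
    ])
    def test_published_split_arithmetic(self, fraction, expected):
        assert split_by_fraction(119_000, fraction) == expected

    def test_bounds(self):
        assert split_by_fraction(10, 1.0) == 10
        with pytest.raises(ValueError):
            split_by_fraction(10, 0.0)


class TestRunConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = RunConfig(canvas_size=32, lagset=(4, 5, 6), data_fraction=0.6, seed=3)
        cfg.to_yaml(tmp_path / "c.yaml")
        loaded = RunConfig.from_yaml(tmp_path / "c.yaml")
        assert loaded == cfg

    def test_validation(self):
        with pytest.raises(ValueError):
            RunConfig(lagset=(5, 3))
        with pytest.raises(ValueError):
            RunConfig(data_fraction=0.33)
        with pytest.raises(ValueError):
            RunConfig(tr_seconds=-1)


class TestManifest:
    def test_manifest_records_config_and_hashes(self, tmp_path):
        src = tmp_path / "input.csv"
        src.write_text("roi,voxel,x,y\n")
        cfg = RunConfig(canvas_size=32, seed=11)
        path = write_manifest(tmp_path / "out", cfg, {"rf": src})
        m = read_manifest(path)
        assert m["seed"] == 11
        assert m["config"]["canvas_size"] == 32
        assert len(m["inputs"]["rf"]["sha256"]) == 64
        assert (tmp_path / "out" / "config.yaml").exists()


class TestCLI:
    def test_help_exits_zero(self):
        assert CliRunner().invoke(main, ["--help"]).exit_code == 0

    def test_unknown_subcommand_nonzero(self):
        assert CliRunner().invoke(main, ["frobnicate"]).exit_code != 0

    def test_simulate_then_preprocess(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "--out", str(tmp_path / "sim"),
                                   "--frames", "20", "--canvas", "16",
                                   "--voxels-per-roi", "64", "--seed", "1"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sim" / "rf_centers.csv").exists()
        assert (tmp_path / "sim" / "manifest.json").exists()
        res = runner.invoke(main, [
            "preprocess", "--video", str(tmp_path / "sim" / "video"),
            "--rf-csv", str(tmp_path / "sim" / "rf_centers.csv"),
            "--responses", str(tmp_path / "sim" / "responses.h5"),
            "--out", str(tmp_path / "pre"), "--canvas", "16",
            "--lagset", "4,5,6"])
        assert res.exit_code == 0, res.output
        stacks, kept, attrs = load_rfs_stacks(tmp_path / "pre" / "rfs.h5")
        assert stacks.shape[1] == 9  # 3 ROIs x 3 lags
        alignment = json.loads((tmp_path / "pre" / "alignment.json").read_text())
        assert alignment["0"] == [4, 5, 6]


def test_manifest_seed_regenerates_outputs_bit_identically(tmp_path):
    """Deterministic stages can be regenerated from their manifest + seed."""
    runner = CliRunner()
    for d in ("a", "b"):
        res = runner.invoke(main, ["simulate", "--out", str(tmp_path / d),
                                   "--frames", "10", "--canvas", "16",
                                   "--voxels-per-roi", "32", "--seed", "42"])
        assert res.exit_code == 0, res.output
    assert ((tmp_path / "a" / "rf_centers.csv").read_bytes()
            == (tmp_path / "b" / "rf_centers.csv").read_bytes())
    assert ((tmp_path / "a" / "video" / "frame_000003.png").read_bytes()
            == (tmp_path / "b" / "video" / "frame_000003.png").read_bytes())
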