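"""Synthetic retinotopy, BOLD-like responses and toy video.

The generator emulates the structure of a single-participant naturalistic
video fMRI session: three early-visual pseudo-ROIs (V1s, V2s, V3s) whose
voxels tile the stimulus canvas with receptive-field centers jittered more
in higher areas (receptive-field scatter grows along the hierarchy), a
repetition time of 0.7 s, and voxel responses that follow the luminance of
the video at each voxel's RF center with a fixed hemodynamic delay of 5 TR
plus Gaussian noise, z-scored per voxel — the same generative structure the
reconstruction model assumes. It deliberately omits an HRF shape,
physiological noise spectra and head motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rf_transport import (
    Canvas, RFCenterTable, VoxelSeries, build_point_transport, zscore,
)

__all__ = [
    "SyntheticRetinotopy", "SyntheticSession", "make_retinotopy",
    "simulate_voxels", "passthrough_rfs", "make_toy_video", "DEFAULT_ROIS",
]

DEFAULT_ROIS = ("V1s", "V2s", "V3s")
DEFAULT_JITTER_SDS = (0.5, 1.0, 1.5)    # RF scatter grows along the hierarchy
TR_SECONDS = 0.7
DEFAULT_LAG_TR = 5


@dataclass
class SyntheticRetinotopy:
    tables: dict[str, RFCenterTable]
    canvas: Canvas
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def roi_order(self) -> tuple[str, ...]:
        return tuple(self.tables)


@dataclass
class SyntheticSession:
    video: np.ndarray                       # [T, H, W, 3] in [0, 1]
    series: dict[str, VoxelSeries]          # z-scored responses per ROI
    retinotopy: SyntheticRetinotopy
    lag_tr: int
    noise_sd: float
    seed: int


def _coverage(table: RFCenterTable, canvas: Canvas) -> float:
    op = build_point_transport(table, canvas)
    return float((op.coverage_count > 0).mean())


def make_retinotopy(n_voxels_per_roi: int | dict[str, int] | None = None,
                    canvas: Canvas = Canvas(),
                    jitter_sds: tuple[float, ...] = DEFAULT_JITTER_SDS,
                    seed: int = 0,
                    rois: tuple[str, ...] = DEFAULT_ROIS,
                    fisheye_strength: float = 0.0) -> SyntheticRetinotopy:
    """Topographic pseudo-ROIs tiling the canvas.

    Each ROI lays one base center per pixel (cycled/subsampled when the voxel
    count differs from the pixel count), adds Gaussian jitter with the ROI's
    scatter, and clips into the canvas. With ``fisheye_strength > 0`` the
    base grid is pulled toward the center following the same radial law as
    the stimulus fish-eye warp, emulating cortical magnification of the
    fovea. Zero jitter and one voxel per pixel give the identity layout.
    """
    rng = np.random.default_rng([seed, 11])
    if n_voxels_per_roi is None:
        n_voxels_per_roi = canvas.n_pixels
    if isinstance(n_voxels_per_roi, int):
        n_voxels_per_roi = {roi: n_voxels_per_roi for roi in rois}
    tables, coverage = {}, {}
    yy, xx = np.divmod(np.arange(canvas.n_pixels), canvas.width)
    for roi, sd in zip(rois, jitter_sds):
        n = n_voxels_per_roi[roi]
        if n < 1:
            raise ValueError("need at least one voxel per ROI")
        base_idx = (np.linspace(0, canvas.n_pixels - 1, n).round().astype(int)
                    if n <= canvas.n_pixels
                    else np.arange(n) % canvas.n_pixels)
        bx, by = xx[base_idx].astype(float), yy[base_idx].astype(float)
        if fisheye_strength > 0:
            c = (canvas.width - 1) / 2.0
            radius = canvas.width / 2.0
            r = np.hypot(bx - c, by - c)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(r > 0, (r / radius) ** (1 + fisheye_strength)
                                 * radius / np.maximum(r, 1e-12), 1.0)
            bx, by = c + (bx - c) * scale, c + (by - c) * scale
        x = np.clip(bx + rng.normal(0, sd, n) if sd > 0 else bx, 0, canvas.width - 1e-9)
        y = np.clip(by + rng.normal(0, sd, n) if sd > 0 else by, 0, canvas.height - 1e-9)
        tables[roi] = RFCenterTable(roi, x, y)
        coverage[roi] = _coverage(tables[roi], canvas)
    return SyntheticRetinotopy(tables, canvas, coverage)


def _sample_at_centers(frame_lum: np.ndarray, table: RFCenterTable) -> np.ndarray:
    """Bilinear luminance at RF centers; coordinates index pixel centers."""
    return ndimage.map_coordinates(frame_lum, [table.y, table.x], order=1,
                                   mode="nearest")


def luminance(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    return frames.mean(axis=-1) if frames.shape[-1] == 3 else frames


def simulate_voxels(video: np.ndarray, retinotopy: SyntheticRetinotopy,
                    lag_tr: int = DEFAULT_LAG_TR, noise_sd: float = 0.1,
                    seed: int = 0, standardize: bool = True) -> SyntheticSession:
    """Delayed, noisy voxel responses to a video, one timepoint per TR.

    Response of voxel v at time t is the luminance of frame (t - lag)
    sampled bilinearly at its RF center, plus N(0, noise_sd), then z-scored
    per voxel over the run (``standardize=False`` keeps raw responses).
    Timepoints before the lag see a zero baseline.
    """
    video = np.asarray(video, dtype=float)
    t_total = len(video)
    if t_total <= lag_tr:
        raise ValueError("video must be longer than the hemodynamic lag")
    rng = np.random.default_rng([seed, 13])
    lum = luminance(video)
    series = {}
    for roi, table in retinotopy.tables.items():
        resp = np.zeros((t_total, table.n_voxels))
        for t in range(lag_tr, t_total):
            resp[t] = _sample_at_centers(lum[t - lag_tr], table)
        if noise_sd > 0:
            resp = resp + rng.normal(0, noise_sd, resp.shape)
        series[roi] = VoxelSeries(roi, zscore(resp) if standardize else resp,
                                  tr_seconds=TR_SECONDS)
    return SyntheticSession(video, series, retinotopy, lag_tr, noise_sd, seed)


def passthrough_rfs(stimuli: np.ndarray, retinotopy: SyntheticRetinotopy,
                    n_lags: int = 1) -> np.ndarray:
    """Stimulus-driven RFS images for the feasibility ("pass-through") test.

    The "voxel responses" are the stimulus luminance values at the RF
    centers — no brain data, no delay — transported straight back to pixel
    space. Returns [n_stimuli, n_rois * n_lags, H, W]; with several lags the
    channels of a ROI are identical copies, matching the input layout of the
    temporal model.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    lum = luminance(stimuli)
    ops = {roi: build_point_transport(t, retinotopy.canvas)
           for roi, t in retinotopy.tables.items()}
    n = len(stimuli)
    h, w = retinotopy.canvas.height, retinotopy.canvas.width
    rois = retinotopy.roi_order
    out = np.empty((n, len(rois) * n_lags, h, w))
    for r_i, roi in enumerate(rois):
        table = retinotopy.tables[roi]
        resp = np.stack([_sample_at_centers(lum[i], table) for i in range(n)])
        imgs = (ops[roi].weights @ resp.T).T.reshape(n, h, w)
        for l in range(n_lags):
            out[:, r_i * n_lags + l] = imgs
    return out


def make_toy_video(t_frames: int, canvas: Canvas = Canvas(), seed: int = 0
                   ) -> np.ndarray:
    """Moving bright shapes (disc, bar, face-like blob) on a dark background.

    Deterministic per seed; values in [0, 1]; shape [T, H, W, 3].
    """
    rng = np.random.default_rng([seed, 17])
    h, w = canvas.height, canvas.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.zeros((t_frames, h, w, 3))
    # per-shape trajectory parameters
    phases = rng.uniform(0, 2 * np.pi, 6)
    speeds = rng.uniform(0.05, 0.15, 6)
    colors = rng.uniform(0.6, 1.0, (3, 3))
    disc_r = h / 8.0
    for t in range(t_frames):
        img = np.full((h, w, 3), 0.05)
        # disc
        cx = w / 2 + 0.35 * w * np.sin(speeds[0] * t + phases[0])
        cy = h / 2 + 0.35 * h * np.cos(speeds[1] * t + phases[1])
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= disc_r**2
        img[m] = colors[0]
        # vertical bar
        bx = (w / 2 + 0.4 * w * np.sin(speeds[2] * t + phases[2]))
        m = np.abs(xx - bx) <= w / 16.0
        img[m] = colors[1]
        # face-like blob: bright ellipse with two dark "eyes"
        fx = w / 2 + 0.3 * w * np.sin(speeds[3] * t + phases[3])
        fy = h / 2 + 0.3 * h * np.sin(speeds[4] * t + phases[4])
        m = ((xx - fx) / (h / 7.0)) ** 2 + ((yy - fy) / (h / 5.5)) ** 2 <= 1
        img[m] = colors[2]
        for ex in (-h / 20.0, h / 20.0):
            me = (xx - (fx + ex)) ** 2 + (yy - (fy - h / 30.0)) ** 2 <= (h / 40.0) ** 2
            img[me] = 0.1
        frames[t] = img
    return np.clip(frames, 0.0, 1.0)
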