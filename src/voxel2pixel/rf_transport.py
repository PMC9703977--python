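"""Receptive-field transport: from voxel responses to images in stimulus space.

Early visual cortex is retinotopically organized: each voxel responds to a
restricted region of the visual field summarized by a receptive-field (RF)
center (x, y) in stimulus/pixel coordinates. Painting each voxel's response
at its RF center turns a 1-D voxel vector into a 2-D "receptive-field signal
image" (RFS image) that shares the topography of the stimulus, so a fully
convolutional network can translate it back into a picture.

With point-like RFs the transport is: the value of pixel (x', y') is the
mean response of the M(x', y') voxels whose RF center rounds to that pixel;
pixels no voxel maps to stay zero. Equivalently the transport is a sparse
linear operator W of shape [H*W, V] with entries 1/M on covered pixels —
that linear form also admits a learnable perturbation (see
:mod:`voxel2pixel.networks`).

Coordinate convention: 0-based, (x, y) = (column, row); pixel (x', y')
covers the half-open square [x', x'+1) x [y', y'+1). Continuous RF centers
are assigned to the nearest pixel with ties going toward the lower index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Canvas", "RFCenterTable", "VoxelSeries", "TransportOperator",
    "PerturbationMask", "RFSImageStack", "DEFAULT_LAGSET",
    "build_point_transport", "apply_transport", "make_perturbation_mask",
    "stack_lags", "build_rfs_dataset", "fisheye_warp", "zscore",
]

#: Default hemodynamic lag offsets in TR units, centered on a 5-TR delay.
DEFAULT_LAGSET: tuple[int, ...] = (3, 4, 5, 6, 7)


@dataclass(frozen=True)
class Canvas:
    """Square stimulus raster; 96 x 96 for the video-reconstruction setup."""

    height: int = 96
    width: int = 96

    def __post_init__(self):
        if self.height != self.width:
            raise ValueError("canvas must be square")
        if self.height < 8:
            raise ValueError("canvas must be at least 8 pixels")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


def round_half_down(x: np.ndarray) -> np.ndarray:
    """Nearest integer, exact halves toward the lower coordinate."""
    return np.ceil(np.asarray(x, dtype=float) - 0.5).astype(int)


@dataclass
class RFCenterTable:
    """Per-voxel receptive-field centers for one ROI.

    ``x``/``y`` are continuous pixel coordinates inside the canvas;
    ``voxel_index`` is contiguous 0..V-1 after loading.
    """

    roi_label: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) == 0:
            raise ValueError(f"no voxels in ROI {self.roi_label!r}")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("NaN receptive-field coordinates")

    @property
    def n_voxels(self) -> int:
        return len(self.x)

    def validate_inside(self, canvas: Canvas):
        ok = ((self.x >= 0) & (self.x < canvas.width)
              & (self.y >= 0) & (self.y < canvas.height))
        if not ok.all():
            raise ValueError(
                f"{int((~ok).sum())} RF centers outside the canvas in ROI "
                f"{self.roi_label!r}; drop them at load time")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": self.roi_label,
            "voxel": np.arange(self.n_voxels),
            "x": self.x,
            "y": self.y,
        })


@dataclass
class VoxelSeries:
    """Z-scored voxel time series [T, V] for one ROI, sampled every TR."""

    roi_label: str
    values: np.ndarray
    tr_seconds: float = 0.7

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be [T, V]")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def zscore(values: np.ndarray) -> np.ndarray:
    """Per-voxel z-scoring over time; constant voxels map to all-zero."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, keepdims=True)
    out = np.zeros_like(values)
    nonconst = sd.ravel() > 0
    out[:, nonconst] = (values[:, nonconst] - mu[:, nonconst]) / sd[:, nonconst]
    return out


@dataclass
class TransportOperator:
    """Sparse voxel-to-pixel map [H*W, V] with per-pixel coverage counts."""

    roi_label: str
    weights: sp.csr_matrix
    coverage_count: np.ndarray
    canvas: Canvas

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


@dataclass
class PerturbationMask:
    """Boolean delta mask [H*W, V] plus the 1/M normalizer per covered pixel.

    Each voxel maps to exactly one pixel under point RFs, so every column has
    a single True entry. Elementwise product of mask, normalizer and a
    learnable weight array reproduces the fixed transport when the weights
    are all ones.
    """

    roi_label: str
    pixel_index: np.ndarray          # [V] flat pixel index per voxel
    normalizer: np.ndarray           # [V] = 1 / M(pixel of voxel)
    canvas: Canvas

    @property
    def n_voxels(self) -> int:
        return len(self.pixel_index)

    def to_sparse(self) -> sp.csr_matrix:
        v = self.n_voxels
        return sp.csr_matrix(
            (np.ones(v), (self.pixel_index, np.arange(v))),
            shape=(self.canvas.n_pixels, v),
        )


@dataclass
class RFSImageStack:
    """Network input [C, H, W]; channels ordered ROI-major, lag-minor."""

    values: np.ndarray
    stimulus_index: int
    roi_order: tuple[str, ...] = ()
    lagset: tuple[int, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite RFS values")


def _rounded_pixels(rf_table: RFCenterTable, canvas: Canvas) -> np.ndarray:
    rf_table.validate_inside(canvas)
    px = np.clip(round_half_down(rf_table.x), 0, canvas.width - 1)
    py = np.clip(round_half_down(rf_table.y), 0, canvas.height - 1)
    return py * canvas.width + px


def build_point_transport(rf_table: RFCenterTable, canvas: Canvas) -> TransportOperator:
    """Point-RF transport: pixel value = mean response of voxels mapping there.

    Centers are assigned by nearest-pixel rounding with exact halves toward
    the lower index; in-canvas coordinates within half a pixel of the upper
    border are kept on the edge pixel.
    """
    flat = _rounded_pixels(rf_table, canvas)
    counts = np.bincount(flat, minlength=canvas.n_pixels)
    v = rf_table.n_voxels
    weights = sp.csr_matrix(
        (1.0 / counts[flat], (flat, np.arange(v))),
        shape=(canvas.n_pixels, v),
    )
    return TransportOperator(
        roi_label=rf_table.roi_label,
        weights=weights,
        coverage_count=counts.reshape(canvas.height, canvas.width),
        canvas=canvas,
    )


def apply_transport(op: TransportOperator, responses: np.ndarray) -> np.ndarray:
    """Linear transport of a voxel response vector into an [H, W] image."""
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (op.n_voxels,):
        raise ValueError(
            f"expected {op.n_voxels} responses, got shape {responses.shape}")
    if not np.isfinite(responses).all():
        raise ValueError("non-finite responses")
    img = op.weights @ responses
    return img.reshape(op.canvas.height, op.canvas.width)


def make_perturbation_mask(rf_table: RFCenterTable, canvas: Canvas) -> PerturbationMask:
    """Delta mask + 1/M normalizer whose product with all-ones weights equals
    the fixed point transport."""
    flat = _rounded_pixels(rf_table, canvas)
    counts = np.bincount(flat, minlength=canvas.n_pixels)
    return PerturbationMask(
        roi_label=rf_table.roi_label,
        pixel_index=flat,
        normalizer=1.0 / counts[flat],
        canvas=canvas,
    )


def stack_lags(series: VoxelSeries, op: TransportOperator, n_stimuli: int,
               lagset=DEFAULT_LAGSET) -> tuple[np.ndarray, list[int]]:
    """Transport lag-shifted response volumes for each stimulus frame.

    For stimulus i and lag k the channel image is the transport of the
    response volume at timepoint i + k: the brain signal recorded k TRs
    after the frame was shown. Returns (images [n_kept, n_lags, H, W],
    kept stimulus indices); stimuli whose lagged volumes run past the end of
    the series are excluded.
    """
    lagset = tuple(int(k) for k in lagset)
    if len(lagset) == 0:
        raise ValueError("lagset must not be empty")
    if list(lagset) != sorted(lagset):
        raise ValueError("lagset must be sorted ascending")
    if series.n_voxels != op.n_voxels:
        raise ValueError("series voxel count does not match operator")
    t_max = series.n_timepoints
    kept = [i for i in range(n_stimuli) if i + lagset[-1] < t_max]
    dropped = n_stimuli - len(kept)
    if dropped:
        logger.info("stack_lags: excluded %d stimuli whose lags exceed T=%d",
                    dropped, t_max)
    h, w = op.canvas.height, op.canvas.width
    out = np.empty((len(kept), len(lagset), h, w))
    # one sparse matmul per lag over all kept stimuli at once
    for j, k in enumerate(lagset):
        idx = np.asarray(kept) + k
        imgs = op.weights @ series.values[idx].T  # [H*W, n_kept]
        out[:, j] = imgs.T.reshape(len(kept), h, w)
    return out, kept


def build_rfs_dataset(series_by_roi: dict[str, VoxelSeries],
                      ops_by_roi: dict[str, TransportOperator],
                      n_stimuli: int,
                      lagset=DEFAULT_LAGSET,
                      roi_order: tuple[str, ...] | None = None
                      ) -> tuple[np.ndarray, list[int], tuple[str, ...]]:
    """Assemble the full multi-ROI input [n_kept, n_rois*n_lags, H, W].

    Channel order is ROI-major, lag-minor: (roi0-lag0, roi0-lag1, ...,
    roi1-lag0, ...). All ROIs must share the kept-stimulus set, which holds
    whenever their series have equal length.
    """
    roi_order = tuple(roi_order or sorted(series_by_roi))
    blocks, kept_ref = [], None
    for roi in roi_order:
        imgs, kept = stack_lags(series_by_roi[roi], ops_by_roi[roi], n_stimuli, lagset)
        if kept_ref is None:
            kept_ref = kept
        elif kept != kept_ref:
            raise ValueError("ROIs disagree on kept stimuli (unequal series lengths)")
        blocks.append(imgs)
    stacked = np.concatenate(blocks, axis=1)
    return stacked, kept_ref, roi_order


def fisheye_warp(image: np.ndarray, strength: float = 0.5) -> np.ndarray:
    """Radial fish-eye remap mimicking retinal eccentricity scaling.

    Destination radius r_dst (from the canvas center) samples the source at
    r_src = R * (r_dst / R) ** (1 + strength) with R the half-width of the
    square canvas, so the center is magnified and the periphery compressed.
    Bilinear sampling; out-of-bounds sources read as 0. strength = 0 is the
    identity up to interpolation.
    """
    image = np.asarray(image, dtype=float)
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    if image.ndim == 2:
        return fisheye_warp(image[..., None], strength)[..., 0]
    h, w = image.shape[:2]
    if h != w:
        raise ValueError("fish-eye warp requires a square image")
    c = (h - 1) / 2.0
    radius = w / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - c, yy - c
    r_dst = np.hypot(dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(r_dst > 0, (r_dst / radius) ** (1 + strength) * radius / r_dst, 1.0)
    src_x = c + dx * scale
    src_y = c + dy * scale
    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        out[..., ch] = ndimage.map_coordinates(
            image[..., ch], [src_y, src_x], order=1, mode="constant", cval=0.0)
    return out
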