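"""Format readers/writers, preprocessing, run configuration and manifests.

RF-center tables travel as CSV (``roi,voxel,x,y``; pixel coordinates,
0-based, column = x). Voxel series can be extracted from a 4D NIfTI volume
with per-ROI binary masks (voxel order = C-order scan of the mask). RFS
image stacks, responses and reconstructions persist as HDF5; run manifests
as JSON with content hashes of the inputs.

Video input supports a directory of numbered PNG frames or a .npy/.npz
array natively; container formats (MP4/WebM) are attempted through imageio
and require an ffmpeg plugin.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .rf_transport import Canvas, RFCenterTable, VoxelSeries, zscore, DEFAULT_LAGSET

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "load_rf_centers", "save_rf_centers", "extract_voxel_series",
    "save_rfs_stacks", "load_rfs_stacks", "save_frames_png", "load_video_frames",
    "resample_video", "split_by_fraction", "write_manifest", "read_manifest",
]

VALID_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RunConfig:
    """Validated run configuration; a serialized copy accompanies every output."""

    canvas_size: int = 96
    rois: tuple[str, ...] = ("V1", "V2", "V3")
    lagset: tuple[int, ...] = DEFAULT_LAGSET
    tr_seconds: float = 0.7
    loss_weights: tuple[float, float, float] = (1.0, 100.0, 1.0)
    learning_rate: float = 2e-4
    beta1: float = 0.5
    batch_size: int = 16
    epochs: int = 50
    data_fraction: float = 1.0
    use_adv: bool = True
    use_feat: bool = True
    learned_rf: bool = False
    fisheye_strength: float = 0.5
    base_width: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.canvas_size < 8:
            raise ValueError("canvas_size must be >= 8")
        if not self.rois:
            raise ValueError("at least one ROI required")
        if not self.lagset or list(self.lagset) != sorted(self.lagset):
            raise ValueError("lagset must be non-empty and sorted")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not any(np.isclose(self.data_fraction, f) for f in VALID_FRACTIONS):
            raise ValueError(f"data_fraction must be one of {VALID_FRACTIONS}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.rois = tuple(self.rois)
        self.lagset = tuple(int(k) for k in self.lagset)
        self.loss_weights = tuple(float(w) for w in self.loss_weights)

    @property
    def canvas(self) -> Canvas:
        return Canvas(self.canvas_size, self.canvas_size)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# -- RF centers ---------------------------------------------------------------

def load_rf_centers(path, canvas: Canvas) -> dict[str, RFCenterTable]:
    """Read a roi,voxel,x,y CSV; drop out-of-canvas voxels with a logged
    count and reindex voxels contiguously per ROI."""
    df = pd.read_csv(path)
    required = {"roi", "voxel", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"RF table must have columns {sorted(required)}")
    if df[["x", "y"]].isna().any().any():
        raise ValueError("NaN coordinates in RF table")
    inside = ((df.x >= 0) & (df.x < canvas.width)
              & (df.y >= 0) & (df.y < canvas.height))
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("dropped %d RF centers outside the %dx%d canvas",
                    n_dropped, canvas.height, canvas.width)
    df = df[inside]
    tables = {}
    for roi, grp in df.groupby("roi", sort=False):
        grp = grp.sort_values("voxel")
        tables[str(roi)] = RFCenterTable(str(roi), grp.x.to_numpy(), grp.y.to_numpy())
    if not tables:
        raise ValueError("no voxels remain inside the canvas")
    return tables


def save_rf_centers(path, tables: dict[str, RFCenterTable]):
    pd.concat([t.to_frame() for t in tables.values()], ignore_index=True) \
        .to_csv(path, index=False)


# -- NIfTI extraction ---------------------------------------------------------

def extract_voxel_series(bold_path, mask_paths: dict[str, object],
                         tr_seconds: float = 0.7,
                         standardize: bool = True) -> dict[str, VoxelSeries]:
    """Extract per-ROI [T, V] series from a 4D BOLD NIfTI and binary masks.

    Voxel order is the C-order scan of the mask array (documented contract:
    the RF-center table must list voxels in the same order).
    """
    import nibabel as nib

    bold = np.asanyarray(nib.load(str(bold_path)).dataobj)
    if bold.ndim != 4:
        raise ValueError("BOLD image must be 4D")
    series = {}
    for roi, mpath in mask_paths.items():
        mask = np.asanyarray(nib.load(str(mpath)).dataobj) > 0
        if mask.shape != bold.shape[:3]:
            raise ValueError(f"mask shape mismatch for ROI {roi!r}")
        vals = bold[mask].T.astype(float)    # [T, V] in mask C-order
        series[roi] = VoxelSeries(roi, zscore(vals) if standardize else vals,
                                  tr_seconds=tr_seconds)
    return series


# -- HDF5 persistence ---------------------------------------------------------

def save_rfs_stacks(path, stacks: np.ndarray, roi_order, lagset, canvas: Canvas,
                    stimulus_indices=None):
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rfs", data=np.asarray(stacks))
        d.attrs["roi_order"] = [str(r) for r in roi_order]
        d.attrs["lagset"] = list(lagset)
        d.attrs["canvas"] = [canvas.height, canvas.width]
        if stimulus_indices is not None:
            f.create_dataset("stimulus_index", data=np.asarray(stimulus_indices))


def load_rfs_stacks(path):
    with h5py.File(path, "r") as f:
        d = f["rfs"]
        attrs = {
            "roi_order": tuple(str(r) for r in d.attrs["roi_order"]),
            "lagset": tuple(int(k) for k in d.attrs["lagset"]),
            "canvas": Canvas(*[int(v) for v in d.attrs["canvas"]]),
        }
        stacks = d[...]
        idx = f["stimulus_index"][...] if "stimulus_index" in f else None
    return stacks, idx, attrs


def save_voxel_series(path, series: dict[str, VoxelSeries]):
    with h5py.File(path, "w") as f:
        for roi, s in series.items():
            d = f.create_dataset(roi, data=s.values)
            d.attrs["tr_seconds"] = s.tr_seconds


def load_voxel_series(path) -> dict[str, VoxelSeries]:
    out = {}
    with h5py.File(path, "r") as f:
        for roi in f:
            out[str(roi)] = VoxelSeries(str(roi), f[roi][...],
                                        tr_seconds=float(f[roi].attrs["tr_seconds"]))
    return out


# -- video --------------------------------------------------------------------

def save_frames_png(directory, frames: np.ndarray):
    """Write frames ([T, H, W, 3], values in [0, 1]) as frame_%06d.png."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(np.asarray(frames)):
        iio.imwrite(directory / f"frame_{i:06d}.png",
                    (np.clip(frame, 0, 1) * 255).astype(np.uint8))


def load_video_frames(path) -> tuple[np.ndarray, float | None]:
    """Load frames from a PNG directory, .npy/.npz, or (via imageio) a
    container file. Returns (frames [T, H, W, 3] in [0, 1], source fps or
    None when unknown)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames in {path}")
        import imageio.v3 as iio
        frames = np.stack([iio.imread(f) for f in files]).astype(float) / 255.0
        fps = None
        meta = path / "fps.txt"
        if meta.exists():
            fps = float(meta.read_text().strip())
        return frames, fps
    if path.suffix in (".npy", ".npz"):
        if path.suffix == ".npy":
            return np.load(path).astype(float), None
        with np.load(path) as z:
            return z["frames"].astype(float), float(z["fps"]) if "fps" in z else None
    try:
        import imageio.v3 as iio
        frames = iio.imread(path, plugin="pyav")
        meta = iio.immeta(path, plugin="pyav")
        return np.asarray(frames).astype(float) / 255.0, meta.get("fps")
    except Exception as exc:    # no ffmpeg plugin offline
        raise ValueError(
            f"cannot decode {path}; use a PNG-sequence directory or "
            f".npy/.npz frames ({exc})") from exc


def resample_video(path_or_frames, canvas: Canvas, tr_seconds: float = 0.7,
                   source_fps: float | None = None) -> np.ndarray:
    """Resample a video to one frame per TR at canvas resolution.

    Temporal resampling picks, for each target timestamp k * tr (k = 0 ..
    floor(duration/tr) - 1), the nearest source frame by timestamp. Spatial
    resampling is bilinear to (canvas, canvas). Target rate 1/tr: 0.7 s
    gives 1.42857142857 frames per second.
    """
    from scipy.ndimage import zoom

    if isinstance(path_or_frames, (str, Path)):
        frames, fps = load_video_frames(path_or_frames)
        source_fps = source_fps or fps
    else:
        frames = np.asarray(path_or_frames, dtype=float)
    if source_fps is None:
        raise ValueError("source fps unknown; pass source_fps")
    n_src = len(frames)
    duration = n_src / source_fps
    n_out = int(np.floor(duration / tr_seconds + 1e-9))    # guard float ratio
    t_targets = np.arange(n_out) * tr_seconds
    src_idx = np.clip(np.round(t_targets * source_fps).astype(int), 0, n_src - 1)
    picked = frames[src_idx]
    h, w = picked.shape[1:3]
    if (h, w) != (canvas.height, canvas.width):
        factors = (1, canvas.height / h, canvas.width / w, 1)
        picked = zoom(picked, factors, order=1)
    return np.clip(picked, 0.0, 1.0)


def split_by_fraction(n_frames: int, fraction: float) -> int:
    """Training-set size for a data-fraction condition: floor(n * fraction),
    taken as a contiguous prefix of the run."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    # tiny guard so binary representations of p/q fractions floor exactly
    return int(np.floor(n_frames * fraction + 1e-9))


# -- manifests ----------------------------------------------------------------

def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, input_paths: dict[str, object],
                   extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "inputs": {name: {"path": str(p), "sha256": _hash_file(p)}
                   for name, p in input_paths.items() if Path(p).is_file()},
        "extra": extra or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    config.to_yaml(out_dir / "config.yaml")
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
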