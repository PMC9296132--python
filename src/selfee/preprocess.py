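"""Frame normalization, live-frame construction, and the single-animal tracker.

The preprocessing recipe for raw top-view videos is: crop to the arena,
resize, subtract the per-pixel mean frame, zero out residuals below a noise
threshold (default 25), median-filter (kernel 5), and histogram-equalize.
Live-frames then stack three temporally offset grayscale frames into the
R/G/B channels so that short-range motion shows up as color.

For open-field interpretation, :func:`track_centroid` reproduces the simple
tracker (threshold 150, median kernel 5, largest connected component,
center of gravity) and :func:`wall_distances` converts a track into
distances to the two nearest arena walls in cm.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "FrameStore",
    "LiveFrame",
    "remove_background",
    "build_live_frames",
    "track_centroid",
    "wall_distances",
]


@dataclass
class FrameStore:
    """An ordered stack of equally shaped grayscale frames for one video."""

    frames: np.ndarray  # (T, H, W) uint8
    video_id: str = "video"
    fps: float | None = None
    crop_box: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1) applied
    target_size: tuple[int, int] | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_array(cls, frames, video_id="video", **kw) -> "FrameStore":
        return cls(np.asarray(frames, dtype=np.uint8), video_id=video_id, **kw)

    @classmethod
    def from_directory(cls, path, video_id: str | None = None,
                       crop_box=None, target_size=None, max_frames=None) -> "FrameStore":
        """Read a directory of PNG/JPG frames, sorted by numeric file name."""
        import imageio.v3 as iio

        path = Path(path)
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")],
            key=lambda p: _numeric_key(p.stem))
        if not files:
            raise FileNotFoundError(f"no PNG/JPG frames in {path}")
        if max_frames is not None:
            files = files[:max_frames]
        frames = []
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:
                img = img.mean(axis=2)
            img = np.asarray(img, dtype=np.uint8)
            if crop_box is not None:
                x0, y0, x1, y1 = crop_box
                img = img[y0:y1, x0:x1]
            if target_size is not None:
                img = _resize_u8(img, target_size)
            frames.append(img)
        return cls(np.stack(frames), video_id=video_id or path.name,
                   crop_box=crop_box, target_size=target_size)

    def to_directory(self, out_dir, stride: int | None = None) -> Path:
        """Write frames as ``%06d.png`` plus a manifest.json."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            iio.imwrite(out / f"{i:06d}.png", frame)
        manifest = {
            "video_id": self.video_id,
            "n_frames": int(len(self)),
            "crop_box": list(self.crop_box) if self.crop_box else None,
            "target_size": list(self.shape),
        }
        if stride is not None:
            manifest["stride"] = int(stride)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out


@dataclass
class LiveFrame:
    """3-channel motion-colored image: R/G/B = frames c-stride, c, c+stride."""

    image: np.ndarray  # (H, W, 3) uint8
    center_index: int
    stride: int

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("live-frame image must be H x W x 3")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def _numeric_key(stem: str):
    m = re.search(r"\d+", stem)
    return (int(m.group()) if m else 0, stem)


def _resize_u8(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize preserving the uint8 range."""
    out = _sk_resize(img.astype(float), size, order=1, preserve_range=True,
                     anti_aliasing=False)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _equalize_hist_u8(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization with the cdf-min convention, so the
    dominant dark background maps back to 0."""
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = hist.cumsum()
    nz = cdf[cdf > 0]
    if len(nz) == 0:
        return img.copy()
    cdf_min = nz[0]
    total = cdf[-1]
    if total == cdf_min:
        return img.copy()
    lut = np.round((cdf - cdf_min) / (total - cdf_min) * 255.0)
    return np.clip(lut, 0, 255).astype(np.uint8)[img]


def remove_background(store: FrameStore, noise_threshold: int = 25,
                      median_kernel: int = 5, equalize: bool = True) -> FrameStore:
    """Mean-frame background subtraction, noise gating, median filter,
    optional histogram equalization.

    The background is the per-pixel mean over the whole video; each frame
    becomes ``|frame - background|`` with residuals below ``noise_threshold``
    zeroed, then median-filtered with ``median_kernel``.
    """
    if len(store) < 2:
        raise ValueError("background removal needs at least 2 frames")
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    background = store.frames.astype(float).mean(axis=0)
    out = np.empty_like(store.frames)
    for i, frame in enumerate(store.frames):
        diff = np.abs(frame.astype(float) - background)
        diff[diff < noise_threshold] = 0.0
        diff = np.clip(np.round(diff), 0, 255).astype(np.uint8)
        if median_kernel > 1:
            diff = ndimage.median_filter(diff, size=median_kernel)
        if equalize:
            diff = _equalize_hist_u8(diff)
        out[i] = diff
    return FrameStore(out, video_id=store.video_id, fps=store.fps,
                      crop_box=store.crop_box, target_size=store.target_size)


def build_live_frames(store: FrameStore, stride: int = 1) -> list[LiveFrame]:
    """One live-frame per valid center index ``c in [stride, n-1-stride]``.

    Channel order (R, G, B) = frames (c-stride, c, c+stride); exactly
    ``n - 2*stride`` live-frames come back.  Use stride 1 for fast (fly-style)
    dynamics and stride 2 for slower (mouse-style) dynamics.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(store)
    needed = 2 * stride + 1
    if n < needed:
        raise ValueError(f"need at least {needed} frames for stride {stride}, got {n}")
    frames = store.frames
    out = []
    for c in range(stride, n - stride):
        img = np.stack([frames[c - stride], frames[c], frames[c + stride]], axis=2)
        out.append(LiveFrame(image=img, center_index=c, stride=stride))
    return out


def live_frame_stack(store: FrameStore, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized variant: returns ``(images (n-2s, H, W, 3), center_indices)``."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(store)
    if n < 2 * stride + 1:
        raise ValueError(f"need at least {2 * stride + 1} frames for stride {stride}")
    f = store.frames
    imgs = np.stack([f[:n - 2 * stride], f[stride:n - stride], f[2 * stride:]], axis=3)
    centers = np.arange(stride, n - stride)
    return imgs, centers


def track_centroid(store: FrameStore, threshold: int = 150,
                   median_kernel: int = 5) -> np.ndarray:
    """Single-animal tracker: threshold, median filter, largest connected
    component, center of gravity.

    Returns an (T, 2) array of (x, y) pixel coordinates; frames with no
    component above threshold yield NaN (missing), never an exception.
    """
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    out = np.full((len(store), 2), np.nan)
    for i, frame in enumerate(store.frames):
        mask = frame > threshold
        if median_kernel > 1:
            mask = ndimage.median_filter(mask, size=median_kernel)
        if not mask.any():
            continue
        labels, n_comp = ndimage.label(mask)
        if n_comp == 0:
            continue
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_comp + 1))
        largest = int(np.argmax(areas)) + 1
        cy, cx = ndimage.center_of_mass(labels == largest)
        out[i] = (cx, cy)
    return out


def wall_distances(track: np.ndarray, arena_box: tuple[float, float, float, float],
                   px_per_cm: float) -> np.ndarray:
    """Distances (cm) to the two nearest of the four arena walls, per frame.

    ``arena_box`` is (x0, y0, x1, y1) in px; positions outside are clamped to
    the border.  Returns (T, 2) with the smaller distance first.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    x0, y0, x1, y1 = arena_box
    track = np.asarray(track, dtype=float)
    x = np.clip(track[:, 0], x0, x1)
    y = np.clip(track[:, 1], y0, y1)
    dists = np.stack([x - x0, x1 - x, y - y0, y1 - y], axis=1) / px_per_cm
    dists.sort(axis=1)
    return dists[:, :2]
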