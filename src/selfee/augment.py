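"""Stochastic two-view augmentation of live-frames.

Pipeline order: crop -> rotate -> vertical flip? -> horizontal flip? ->
Turbo colormap? -> color jitter.  The crop keeps at least 49% of the pixels
(side fractions sampled in [0.7, 1]); the rotation angle is bounded by the
acute angle between the image diagonal and the vertical; flips and the
Turbo lookup each fire with probability 0.5; brightness/contrast (and, after
a Turbo transform, saturation/hue) are jittered within +/-10%.

The Turbo transform maps each 8-bit channel through the published 256-entry
Turbo colormap and keeps channel i of Turbo(channel i), so the motion
coloring of a live-frame survives while color distortions gain teeth on
otherwise grayscale channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy import ndimage

__all__ = ["AugmentPolicy", "TURBO_LUT", "apply_turbo", "augment_live_frame"]

# The published 256-entry Turbo colormap as a uint8 lookup table.
TURBO_LUT: np.ndarray = np.round(
    colormaps["turbo"](np.arange(256))[:, :3] * 255.0).astype(np.uint8)


@dataclass
class AugmentPolicy:
    crop_side_fraction_range: tuple[float, float] = (0.7, 1.0)
    max_rotation: float | None = None  # radians; None -> arctan(W/H)
    p_vflip: float = 0.5
    p_hflip: float = 0.5
    p_turbo: float = 0.5
    jitter_fraction: float = 0.10

    def __post_init__(self):
        lo, hi = self.crop_side_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("crop fractions must satisfy 0 < lo <= hi <= 1")
        for p in (self.p_vflip, self.p_hflip, self.p_turbo):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.jitter_fraction < 0:
            raise ValueError("jitter_fraction must be >= 0")


def apply_turbo(image: np.ndarray) -> np.ndarray:
    """Per-channel Turbo lookup: output channel i = Turbo(channel i)[..., i]."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("Turbo lookup requires 8-bit input")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    out = np.empty_like(image)
    for i in range(3):
        out[..., i] = TURBO_LUT[image[..., i], i]
    return out


def _warp(img: np.ndarray, fh: float, fw: float, angle: float,
          rng: np.random.Generator) -> np.ndarray:
    """Crop (uniform placement) + resize back + rotate about the center as
    one composed inverse-affine interpolation per channel; regions exposed
    by the rotation fill black (the background color after preprocessing)."""
    h, w = img.shape[:2]
    ch = max(1, int(round(h * fh)))
    cw = max(1, int(round(w * fw)))
    do_crop = not (ch == h and cw == w)
    if not do_crop and angle == 0.0:
        return img
    if do_crop:
        top = float(rng.integers(0, h - ch + 1))
        left = float(rng.integers(0, w - cw + 1))
        sy, sx = ch / h, cw / w
    else:
        top = left = 0.0
        sy = sx = 1.0
    # rotation inverse map (y, x) -> R^-1 (out - c) + c
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, sa], [-sa, ca]])
    b = np.array([cy, cx]) - rot @ np.array([cy, cx])
    # crop/resize inverse map (half-pixel convention): in = t + (u + .5) s - .5
    scale = np.diag([sy, sx])
    matrix = scale @ rot
    offset = np.array([top, left]) + scale @ (b + 0.5) - 0.5
    out = np.empty_like(img)
    for ci in range(img.shape[2]):
        warped = ndimage.affine_transform(img[..., ci].astype(np.float32), matrix,
                                          offset=offset, order=1, mode="constant",
                                          cval=0.0)
        out[..., ci] = np.clip(np.round(warped), 0, 255).astype(np.uint8)
    return out


def _rgb_to_hsv(x: np.ndarray) -> np.ndarray:
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    maxc = x.max(axis=-1)
    minc = x.min(axis=-1)
    delta = maxc - minc
    v = maxc
    s = np.where(maxc > 0, delta / np.maximum(maxc, 1e-12), 0.0)
    hue = np.zeros_like(maxc)
    nz = delta > 0
    d = np.maximum(delta, 1e-12)
    hr = ((g - b) / d) % 6.0
    hg = (b - r) / d + 2.0
    hb = (r - g) / d + 4.0
    hue = np.where(nz & (maxc == r), hr, hue)
    hue = np.where(nz & (maxc == g) & (maxc != r), hg, hue)
    hue = np.where(nz & (maxc == b) & (maxc != r) & (maxc != g), hb, hue)
    return np.stack([hue / 6.0, s, v], axis=-1)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0] * 6.0, hsv[..., 1], hsv[..., 2]
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    choices = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    r = np.choose(i, [c[0] for c in choices])
    g = np.choose(i, [c[1] for c in choices])
    b = np.choose(i, [c[2] for c in choices])
    return np.stack([r, g, b], axis=-1)


def _color_jitter(img: np.ndarray, j: float, rng: np.random.Generator,
                  full_color: bool) -> np.ndarray:
    """Brightness/contrast always; saturation/hue only for colored images
    (i.e. after a Turbo transform, where they are meaningful)."""
    x = img.astype(np.float32) / 255.0
    b = rng.uniform(1 - j, 1 + j)
    c = rng.uniform(1 - j, 1 + j)
    s = rng.uniform(1 - j, 1 + j)
    hshift = rng.uniform(-j, j)
    x = x * b
    x = x.mean() + (x - x.mean()) * c
    if full_color:
        hsv = _rgb_to_hsv(np.clip(x, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + hshift) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * s, 0, 1)
        x = _hsv_to_rgb(hsv)
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def augment_live_frame(live_image: np.ndarray, policy: AugmentPolicy,
                       rng: np.random.Generator) -> np.ndarray:
    """One stochastic view of a live-frame (uint8 H x W x 3 in, same out).

    With every stochastic component disabled (crop range (1, 1), zero max
    rotation, zero flip/Turbo probabilities, zero jitter) this is the
    identity.
    """
    img = np.asarray(live_image)
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a uint8 H x W x 3 live-frame")
    h, w = img.shape[:2]
    lo, hi = policy.crop_side_fraction_range
    if (lo, hi) != (1.0, 1.0):
        fh = rng.uniform(lo, hi)
        fw = rng.uniform(lo, hi)
    else:
        fh = fw = 1.0
    theta_max = policy.max_rotation if policy.max_rotation is not None else np.arctan(w / h)
    angle = rng.uniform(-theta_max, theta_max) if theta_max > 0 else 0.0
    img = _warp(img, fh, fw, angle, rng)
    if policy.p_vflip > 0 and rng.random() < policy.p_vflip:
        img = img[::-1].copy()
    if policy.p_hflip > 0 and rng.random() < policy.p_hflip:
        img = img[:, ::-1].copy()
    turbo_applied = False
    if policy.p_turbo > 0 and rng.random() < policy.p_turbo:
        img = apply_turbo(img)
        turbo_applied = True
    if policy.jitter_fraction > 0:
        img = _color_jitter(img, policy.jitter_fraction, rng, full_color=turbo_applied)
    return img
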