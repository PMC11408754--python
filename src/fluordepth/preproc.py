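"""Camera-resolution preprocessing for phantom/experimental SFDI images.

Experimental stacks arrive at 0.1 mm/pixel with a manual crop of varying
size.  The chain pads each channel with draws from the non-fluorescent
background statistics to at least 505 x 505 pixels, crops to exactly
505 x 505, and box-downsamples (non-overlapping 5 x 5 block means) to the
network's 101 x 101 grid at 0.5 mm/pixel.  The same chain applies to
reflectance, fluorescence and optical-property channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CAMERA_PIXEL_MM",
    "NETWORK_PIXEL_MM",
    "TARGET_CAMERA_SHAPE",
    "BackgroundStats",
    "pad_with_background",
    "box_downsample",
    "preprocess_stack",
]

CAMERA_PIXEL_MM = 0.1
NETWORK_PIXEL_MM = 0.5
TARGET_CAMERA_SHAPE = (505, 505)  # 50.5 mm field of view at camera resolution
_BLOCK = int(round(NETWORK_PIXEL_MM / CAMERA_PIXEL_MM))


@dataclass(frozen=True)
class BackgroundStats:
    """Mean and SD of the non-tumor (non-fluorescent agar) background."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("background SD must be >= 0")


def pad_with_background(
    image: np.ndarray,
    stats: BackgroundStats,
    target_shape: tuple = TARGET_CAMERA_SHAPE,
    rng: np.random.Generator | None = None,
    constant: bool = False,
) -> np.ndarray:
    """Symmetrically pad to the target extent with background-like values.

    Pad pixels are i.i.d. uniform on [mean - SD, mean + SD] (seeded via
    ``rng``); ``constant=True`` uses the mean instead.
    """
    h, w = image.shape
    th, tw = target_shape
    if th < h or tw < w:
        raise ValueError(f"target {target_shape} smaller than image {image.shape}")
    if (th, tw) == (h, w):
        return image.copy()
    top = (th - h) // 2
    left = (tw - w) // 2
    out = np.empty((th, tw), dtype=float)
    if constant:
        out[...] = stats.mean
    else:
        if rng is None:
            raise ValueError("rng required for randomized padding")
        out[...] = rng.uniform(stats.mean - stats.sd, stats.mean + stats.sd, (th, tw))
    out[top : top + h, left : left + w] = image
    return out


def box_downsample(image: np.ndarray) -> np.ndarray:
    """Non-overlapping 5 x 5 block means: 505 x 505 -> 101 x 101."""
    if image.shape != TARGET_CAMERA_SHAPE:
        raise ValueError(
            f"expected a {TARGET_CAMERA_SHAPE[0]}x{TARGET_CAMERA_SHAPE[1]} image "
            f"at {CAMERA_PIXEL_MM} mm/pixel, got {image.shape}"
        )
    n = TARGET_CAMERA_SHAPE[0] // _BLOCK
    return image.reshape(n, _BLOCK, n, _BLOCK).mean(axis=(1, 3))


def preprocess_stack(
    images: dict,
    stats: BackgroundStats,
    crop_box: tuple | None = None,
    rng: np.random.Generator | None = None,
    constant_pad: bool = False,
) -> dict:
    """Crop, pad and downsample a channel dictionary to network inputs.

    ``images`` maps channel names to camera-resolution arrays sharing one
    shape; ``crop_box`` is (row0, col0, row1, col1) applied identically to
    every channel.  Channels are padded with the same seeded draw sequence
    (one child generator per channel, spawned in sorted-key order) and
    box-downsampled to 101 x 101.
    """
    keys = sorted(images)
    shapes = {images[k].shape for k in keys}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes disagree: {shapes}")
    if rng is None:
        rng = np.random.default_rng(0)
    children = rng.spawn(len(keys))
    out = {}
    for k, child in zip(keys, children):
        img = np.asarray(images[k], dtype=float)
        if crop_box is not None:
            r0, c0, r1, c1 = crop_box
            img = img[r0:r1, c0:c1]
        # a generous manual crop is center-trimmed to the exact field of view
        for axis, target in enumerate(TARGET_CAMERA_SHAPE):
            if img.shape[axis] > target:
                lo = (img.shape[axis] - target) // 2
                img = img[lo : lo + target] if axis == 0 else img[:, lo : lo + target]
        padded = pad_with_background(img, stats, rng=child, constant=constant_pad)
        out[k] = box_downsample(padded)
    return out
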