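"""Image canonicalization, augmentation, and dataset splitting.

Crops arrive with arbitrary aspect ratios; they are padded to a square
along the long side (black fill, content centered), bilinearly resized to
the network input size and mapped to [-1, 1].  The augmentation suite
mirrors a 7-variant expansion: brightness down/up, contrast down/up, hue
shift, saturation shift, Gaussian blur.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["ImageRecord", "PARTS", "pad_to_square", "resize_and_normalize",
           "augment", "expand_dataset", "split_dataset", "records_to_arrays",
           "DEFAULT_AUGMENTATIONS"]

PARTS = ("face", "left", "right")


@dataclass
class ImageRecord:
    """One 8-bit RGB part image with its identity and part labels."""

    pixels: np.ndarray  # H x W x 3 uint8
    individual_id: str
    part: str
    source: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit")
        if self.part not in PARTS:
            raise ValueError(f"part must be one of {PARTS}, got {self.part!r}")


def pad_to_square(img: np.ndarray) -> np.ndarray:
    """Pad with black along the short side so content stays centered."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h == w:
        return img
    s = max(h, w)
    top = (s - h) // 2
    left = (s - w) // 2
    out = np.zeros((s, s) + img.shape[2:], dtype=img.dtype)
    out[top:top + h, left:left + w] = img
    return out


def resize_and_normalize(img: np.ndarray, size: int = 299) -> np.ndarray:
    """Bilinear resize of a square image, then x -> x/127.5 - 1."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h != w:
        raise ValueError(f"expected a square image, got {h}x{w}; "
                         "apply pad_to_square first")
    if h != size:
        img = np.asarray(Image.fromarray(img).resize((size, size),
                                                     Image.BILINEAR))
    return (img.astype(np.float32) / 127.5) - 1.0


_IDENTITY = {"brightness": 1.0, "contrast": 1.0, "saturation": 1.0,
             "hue": 0.0, "blur": 0.0}


def augment(img: np.ndarray, kind: str, magnitude: float) -> np.ndarray:
    """One photometric augmentation of an 8-bit RGB image.

    brightness/contrast/saturation are multiplicative factors, hue an
    additive shift on the hue circle (fraction of a turn), blur a Gaussian
    sigma in pixels.  Output is clipped back to valid 8-bit range.
    """
    if kind not in _IDENTITY:
        raise ValueError(f"unknown augmentation kind {kind!r}")
    img = np.asarray(img)
    if magnitude == _IDENTITY[kind]:
        return img.copy()
    x = img.astype(np.float32)
    if kind == "brightness":
        out = x * magnitude
    elif kind == "contrast":
        gray_mean = (x @ np.array([0.299, 0.587, 0.114], dtype=np.float32)).mean()
        out = gray_mean + magnitude * (x - gray_mean)
    elif kind == "saturation":
        gray = x @ np.array([0.299, 0.587, 0.114], dtype=np.float32)
        out = gray[..., None] + magnitude * (x - gray[..., None])
    elif kind == "hue":
        hsv = rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + magnitude) % 1.0
        out = hsv2rgb(hsv) * 255.0
    else:  # blur
        out = np.stack([gaussian_filter(x[..., c], sigma=magnitude)
                        for c in range(3)], axis=-1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


#: The 7-variant expansion: (kind, magnitude) per augmented copy.
DEFAULT_AUGMENTATIONS = (
    ("brightness", 0.7), ("brightness", 1.3),
    ("contrast", 0.7), ("contrast", 1.3),
    ("hue", 0.05), ("saturation", 1.3), ("blur", 1.0),
)


def expand_dataset(records, augmentations=DEFAULT_AUGMENTATIONS):
    """Each record yields itself plus one copy per augmentation; labels
    are inherited, so n records become (1 + len(augmentations)) * n."""
    records = list(records)
    if not records:
        raise ValueError("expand_dataset needs at least one record")
    out = []
    for rec in records:
        out.append(rec)
        for kind, mag in augmentations:
            out.append(replace(rec, pixels=augment(rec.pixels, kind, mag),
                               source=f"{rec.source}+{kind}({mag})"))
    return out


def split_dataset(items, ratios, seed: int):
    """Seeded shuffle, then partition by ``ratios``.

    Every part after the first gets floor(n * ratio/total) items; the first
    part absorbs the remainder, so the partition is disjoint and exhaustive.
    """
    items = list(items)
    ratios = list(ratios)
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if len(ratios) > len(items):
        raise ValueError(f"cannot split {len(items)} items into "
                         f"{len(ratios)} parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n, total = len(items), sum(ratios)
    # 1e-9 guards the floor against float representation of exact ratios
    sizes = [int(np.floor(n * r / total + 1e-9)) for r in ratios]
    sizes[0] = n - sum(sizes[1:])
    parts, start = [], 0
    for size in sizes:
        parts.append([items[i] for i in order[start:start + size]])
        start += size
    return parts


def records_to_arrays(records, size: int, class_order=None):
    """Canonicalize records into (X, y) training arrays.

    Returns (X, y, classes): X (n, size, size, 3) in [-1, 1], y integer
    labels following ``classes`` (sorted individual ids by default).
    """
    records = list(records)
    classes = (sorted({r.individual_id for r in records})
               if class_order is None else list(class_order))
    index = {c: i for i, c in enumerate(classes)}
    X = np.stack([resize_and_normalize(pad_to_square(r.pixels), size)
                  for r in records])
    y = np.array([index[r.individual_id] for r in records], dtype=np.int64)
    return X, y, classes
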