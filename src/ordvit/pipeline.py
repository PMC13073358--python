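"""Image preprocessing, training-time augmentation, and patch geometry.

Preprocessing is deterministic: decode, force RGB, resize to the model's
square input, and per-image min-max normalize to [0, 1] (one min and one max
over all three channels jointly; a degenerate constant image maps to all
zeros).  Augmentation is stochastic and applied only during training: flips,
small rotations with reflection fill, subpixel translations, and brightness/
contrast jitter.  ``patchify`` cuts the frame into non-overlapping P x P
patches in row-major order and flattens each to a length 3*P*P vector; with
the standard 224-pixel input and 16-pixel patches this yields the familiar
14 x 14 = 196-token sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["AugConfig", "PatchGrid", "preprocess", "minmax_normalize", "augment", "patchify", "unpatchify"]


@dataclass(frozen=True)
class AugConfig:
    """Training-time augmentation settings.

    Defaults: flips with probability 0.5 each, rotations uniform in +/-20
    degrees, translations up to 10% of the frame per axis, and brightness and
    contrast scales each uniform in [0.8, 1.2].
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rot_deg_max: float = 20.0
    translate_frac_max: float = 0.10
    brightness_jitter: float = 0.2
    contrast_jitter: float = 0.2
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hflip <= 1.0 and 0.0 <= self.p_vflip <= 1.0):
            raise ValueError("flip probabilities must be in [0, 1]")
        if self.rot_deg_max < 0:
            raise ValueError("rot_deg_max must be >= 0")
        if not (0.0 <= self.translate_frac_max < 1.0):
            raise ValueError("translate_frac_max must be in [0, 1)")


@dataclass(frozen=True)
class PatchGrid:
    """Square patch layout of an image: ``n_patches = (image_size / patch_size)**2``."""

    image_size: int
    patch_size: int

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"patch_size {self.patch_size} does not divide image_size {self.image_size}"
            )

    @property
    def n_side(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.n_side**2


def minmax_normalize(img: np.ndarray) -> np.ndarray:
    """Per-image min-max scaling to [0, 1] over all channels jointly."""
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img, dtype=float)
    return (img.astype(float) - lo) / (hi - lo)


def preprocess(source: str | Path | np.ndarray | Image.Image, target_size: int = 224) -> np.ndarray:
    """Decode, force 3-channel RGB, resize to target x target, min-max normalize.

    Accepts a file path, a PIL image, or an array (H x W grayscale or
    H x W x 3).  Raises OSError for unreadable files so callers can skip and
    log corrupt records.
    """
    if isinstance(source, (str, Path)):
        with Image.open(source) as im:
            pil = im.convert("RGB")
    elif isinstance(source, Image.Image):
        pil = source.convert("RGB")
    else:
        arr = np.asarray(source)
        if arr.ndim == 2:
            arr = np.repeat(arr[..., None], 3, axis=2)
        if arr.dtype != np.uint8:
            # lossless path for float arrays already scaled to [0,1]-ish
            if arr.shape[0] == target_size and arr.shape[1] == target_size:
                return minmax_normalize(arr)
            arr = (np.clip(arr, 0.0, 1.0) * 255).round().astype(np.uint8)
        pil = Image.fromarray(arr, mode="RGB")
    if pil.size != (target_size, target_size):
        pil = pil.resize((target_size, target_size), Image.BILINEAR)
    return minmax_normalize(np.asarray(pil, dtype=float))


def augment(img: np.ndarray, cfg: AugConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply flips, rotation, translation, and photometric jitter, in that order.

    Identity when ``cfg.enabled`` is false.  Rotation and translation use
    reflection fill so no black corners are introduced for the attribution
    maps to latch onto.  Output is clipped to [0, 1].
    """
    if not cfg.enabled:
        return img
    out = img
    if rng.random() < cfg.p_hflip:
        out = out[:, ::-1, :]
    if rng.random() < cfg.p_vflip:
        out = out[::-1, :, :]
    if cfg.rot_deg_max > 0:
        angle = rng.uniform(-cfg.rot_deg_max, cfg.rot_deg_max)
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False, mode="reflect", order=1)
    if cfg.translate_frac_max > 0:
        h, w = out.shape[:2]
        dy = rng.uniform(-cfg.translate_frac_max, cfg.translate_frac_max) * h
        dx = rng.uniform(-cfg.translate_frac_max, cfg.translate_frac_max) * w
        out = ndimage.shift(out, (dy, dx, 0.0), mode="reflect", order=1)
    if cfg.brightness_jitter > 0:
        out = out * rng.uniform(1.0 - cfg.brightness_jitter, 1.0 + cfg.brightness_jitter)
    if cfg.contrast_jitter > 0:
        scale = rng.uniform(1.0 - cfg.contrast_jitter, 1.0 + cfg.contrast_jitter)
        out = (out - out.mean()) * scale + out.mean()
    return np.clip(out, 0.0, 1.0)


def patchify(img: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut into non-overlapping patches, row-major, each flattened to 3*P*P.

    Patch i covers rows [floor(i / n_side) * P, ...) and columns
    [(i mod n_side) * P, ...), half-open and 0-based.
    """
    h, w = img.shape[:2]
    if h % patch_size or w % patch_size:
        raise ValueError(f"patch size {patch_size} does not divide image dims {h}x{w}")
    ny, nx = h // patch_size, w // patch_size
    c = img.shape[2]
    patches = (
        img.reshape(ny, patch_size, nx, patch_size, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(ny * nx, patch_size * patch_size * c)
    )
    return patches


def unpatchify(patches: np.ndarray, image_size: int, patch_size: int, channels: int = 3) -> np.ndarray:
    """Exact inverse of :func:`patchify` for square images."""
    n_side = image_size // patch_size
    return (
        patches.reshape(n_side, n_side, patch_size, patch_size, channels)
        .transpose(0, 2, 1, 3, 4)
        .reshape(image_size, image_size, channels)
    )
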