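"""Synthetic endoscopy-like images with ordinal severity structure.

Real ordinal grading datasets order lesions along a benign-to-malignant
spectrum in which lesion size, border irregularity, internal texture contrast
and vascular density all increase with severity.  This module fabricates RGB
frames that carry exactly that graded signal, together with pixel-accurate
lesion masks, so the classifier and the attribution module can be exercised
and evaluated end to end without any external imagery.

A frame is a smooth mucosa-like pink background (low-frequency colour drift
plus Gaussian pixel noise).  A lesion, when present, is a star-convex blob
whose boundary radius is sinusoidally perturbed,

    r(theta) = r0 * (1 + a * sum_{k=2..5} c_k sin(k*theta + phi_k)),

with the amplitude ``a`` graded by class.  The interior is darkened, given a
high-frequency texture whose contrast is graded by class, and overlaid with
thin dark random-walk curves (a vascular-pattern proxy) whose density is also
graded by class.  Class 0 frames contain no lesion by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "SeverityParams",
    "ImageRecord",
    "render_image",
    "generate_dataset",
    "stratified_split",
    "make_records",
    "load_manifest",
    "load_records",
]

CLASS_NAMES = ("Benign", "Low-Risk", "High-Risk", "Malignant")
N_CLASSES = 4


@dataclass(frozen=True)
class SeverityParams:
    """Generator settings; the three per-class sequences must be non-decreasing.

    ``lesion_area_fracs[c]`` is the approximate fraction of the frame covered
    by the class-``c`` lesion (0 means no lesion), ``border_irregularity[c]``
    the radial perturbation amplitude ``a``, and ``texture_contrast[c]`` the
    peak-to-peak intensity contrast of the interior texture.
    """

    n_per_class: int = 50
    image_size: int = 64
    lesion_area_fracs: tuple[float, float, float, float] = (0.0, 0.05, 0.12, 0.24)
    border_irregularity: tuple[float, float, float, float] = (0.0, 0.08, 0.18, 0.30)
    texture_contrast: tuple[float, float, float, float] = (0.0, 0.12, 0.25, 0.40)
    vessel_counts: tuple[int, int, int, int] = (0, 1, 3, 6)
    background_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lesion_area_fracs", "border_irregularity", "texture_contrast"):
            seq = getattr(self, name)
            if len(seq) != N_CLASSES:
                raise ValueError(f"{name} must have {N_CLASSES} entries")
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be non-decreasing over class index")
        if not all(0.0 <= f <= 1.0 for f in self.lesion_area_fracs):
            raise ValueError("lesion_area_fracs must lie in [0, 1]")
        if self.image_size < 16:
            raise ValueError("image_size too small to place a lesion")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")

    @classmethod
    def well_separated(cls, n_per_class: int = 100, image_size: int = 64, seed: int = 0) -> "SeverityParams":
        """Clearly separated class morphology, used for mechanism-recovery runs."""
        return cls(
            n_per_class=n_per_class,
            image_size=image_size,
            lesion_area_fracs=(0.0, 0.06, 0.16, 0.30),
            border_irregularity=(0.0, 0.10, 0.22, 0.38),
            texture_contrast=(0.0, 0.18, 0.32, 0.50),
            vessel_counts=(0, 1, 4, 8),
            seed=seed,
        )

    @classmethod
    def ordinal_graded(cls, n_per_class: int = 64, image_size: int = 64, seed: int = 0) -> "SeverityParams":
        """Classes 1 and 2 share the same lesion area; only the ordinal-graded
        features (border irregularity, texture contrast, vascular density)
        separate them.  Used to probe the progression-aware module."""
        return cls(
            n_per_class=n_per_class,
            image_size=image_size,
            lesion_area_fracs=(0.0, 0.15, 0.15, 0.30),
            border_irregularity=(0.0, 0.08, 0.30, 0.38),
            texture_contrast=(0.0, 0.12, 0.42, 0.52),
            vessel_counts=(0, 1, 6, 9),
            seed=seed,
        )


@dataclass
class ImageRecord:
    """One RGB frame with its ordinal label, optional lesion mask and split."""

    image_id: str
    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    label: int
    mask: np.ndarray | None = None  # H x W bool
    split: str | None = None

    def __post_init__(self) -> None:
        if self.label not in range(N_CLASSES):
            raise ValueError(f"label must be in 0..{N_CLASSES - 1}, got {self.label}")
        if self.mask is not None and self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixel grid")


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Zero-mean low-frequency noise field, normalized to unit peak amplitude."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _lesion_mask(
    size: int,
    area_frac: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Star-convex blob mask occupying ~area_frac of the frame."""
    r0 = np.sqrt(area_frac * size * size / np.pi)
    margin = min(size / 2.0 - 1.0, r0 * (1.0 + 2.0 * irregularity) + 1.0)
    lo, hi = margin, size - margin
    cy = rng.uniform(lo, hi) if hi > lo else size / 2.0
    cx = rng.uniform(lo, hi) if hi > lo else size / 2.0
    ks = np.arange(2, 6)
    coeffs = rng.uniform(0.3, 1.0, size=4)
    coeffs /= coeffs.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r_theta = r0 * (1.0 + irregularity * np.sum(
        coeffs[:, None, None] * np.sin(ks[:, None, None] * theta[None] + phases[:, None, None]),
        axis=0,
    ))
    return dy * dy + dx * dx <= r_theta * r_theta


def _vessels(mask: np.ndarray, count: int, rng: np.random.Generator) -> np.ndarray:
    """Thin random-walk curves confined to the lesion; returns a darkness field."""
    dark = np.zeros(mask.shape, dtype=float)
    if count == 0 or not mask.any():
        return dark
    ys, xs = np.nonzero(mask)
    n_steps = max(8, int(np.sqrt(mask.sum())))
    for _ in range(count):
        i = rng.integers(len(ys))
        y, x = float(ys[i]), float(xs[i])
        heading = rng.uniform(0.0, 2.0 * np.pi)
        for _ in range(n_steps):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]:
                dark[iy, ix] = 1.0
            heading += rng.normal(0.0, 0.5)
            y += np.sin(heading)
            x += np.cos(heading)
    return ndimage.gaussian_filter(dark, sigma=0.6)


def render_image(class_index: int, params: SeverityParams, rng: np.random.Generator) -> ImageRecord:
    """Render one frame of the given ordinal class with its ground-truth mask.

    Deterministic given the rng state.  The mask is all-zero when the class's
    lesion area fraction is 0.
    """
    if class_index not in range(N_CLASSES):
        raise ValueError(f"class_index must be in 0..{N_CLASSES - 1}, got {class_index}")
    size = params.image_size

    # mucosa-like background: pink base + smooth colour drift + pixel noise
    base = np.array([0.78, 0.45, 0.42])
    drift = _smooth_field((size, size), rng, sigma=size / 6.0)
    img = np.empty((size, size, 3))
    for ch, (b, amp) in enumerate(zip(base, (0.08, 0.05, 0.05))):
        img[..., ch] = b + amp * drift
    img += rng.normal(0.0, params.background_noise_sd, size=(size, size, 3))

    area = params.lesion_area_fracs[class_index]
    if area > 0.0:
        mask = _lesion_mask(size, area, params.border_irregularity[class_index], rng)
        # graded interior: darker, redder, textured
        contrast = params.texture_contrast[class_index]
        texture = _smooth_field((size, size), rng, sigma=1.2)
        interior = np.empty_like(img)
        interior[..., 0] = 0.55 + 0.5 * contrast * texture
        interior[..., 1] = 0.22 + 0.4 * contrast * texture
        interior[..., 2] = 0.25 + 0.4 * contrast * texture
        m3 = mask[..., None]
        img = np.where(m3, interior, img)
        vessels = _vessels(mask, params.vessel_counts[class_index], rng)
        img -= 0.45 * vessels[..., None]
    else:
        mask = np.zeros((size, size), dtype=bool)

    img = np.clip(img, 0.0, 1.0)
    return ImageRecord(image_id="", pixels=img, label=class_index, mask=mask)


def make_records(params: SeverityParams) -> list[ImageRecord]:
    """Generate a balanced in-memory dataset: 4 * n_per_class records."""
    rng = np.random.default_rng(params.seed)
    records = []
    for i in range(params.n_per_class):
        for c in range(N_CLASSES):
            rec = render_image(c, params, rng)
            rec.image_id = f"img_{c}_{i:05d}"
            records.append(rec)
    return records


def _to_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray((np.clip(arr, 0.0, 1.0) * 255).round().astype(np.uint8)).save(path)


def generate_dataset(params: SeverityParams, out_dir: str | Path) -> pd.DataFrame:
    """Generate a balanced dataset on disk and return its manifest.

    Writes 8-bit PNG images and {0,255} PNG masks under ``out_dir`` plus a
    ``manifest.csv`` with columns image_id,image_path,mask_path,label,split.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for rec in make_records(params):
        img_path = img_dir / f"{rec.image_id}.png"
        _to_png(rec.pixels, img_path)
        if rec.mask is not None:
            mask_path = mask_dir / f"{rec.image_id}.png"
            Image.fromarray(np.where(rec.mask, 255, 0).astype(np.uint8)).save(mask_path)
            mask_rel = str(mask_path.relative_to(out_dir))
        else:
            mask_rel = ""
        rows.append(
            {
                "image_id": rec.image_id,
                "image_path": str(img_path.relative_to(out_dir)),
                "mask_path": mask_rel,
                "label": rec.label,
                "split": "",
            }
        )
    manifest = pd.DataFrame(rows, columns=["image_id", "image_path", "mask_path", "label", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n by fractions; totals are exact."""
    ideal = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in ideal]
    shortfall = n - sum(counts)
    remainders = sorted(range(len(fractions)), key=lambda i: ideal[i] - counts[i], reverse=True)
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def stratified_split(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each record to train/val/test, preserving class proportions.

    Per class, split sizes are the largest-remainder rounding of
    ``fraction * class count``, so totals match the class count exactly and
    the three splits partition the manifest.  Deterministic given ``seed``.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    if manifest["label"].isna().any():
        raise ValueError("every record must be labeled")

    out = manifest.copy()
    out["split"] = ""
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")
    for label in sorted(out["label"].unique()):
        idx = out.index[out["label"] == label].to_numpy()
        if len(idx) < 3:
            import warnings

            warnings.warn(f"class {label} has fewer records ({len(idx)}) than splits")
        counts = _largest_remainder(len(idx), fractions)
        perm = rng.permutation(len(idx))
        start = 0
        for name, cnt in zip(names, counts):
            out.loc[idx[perm[start : start + cnt]], "split"] = name
            start += cnt
    return out


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, dtype={"mask_path": str, "split": str})


def load_records(manifest: pd.DataFrame, root: str | Path, split: str | None = None) -> list[ImageRecord]:
    """Load manifest rows (optionally one split) back into ImageRecords."""
    root = Path(root)
    rows = manifest if split is None else manifest[manifest["split"] == split]
    records = []
    for row in rows.itertuples():
        pixels = np.asarray(Image.open(root / row.image_path).convert("RGB"), dtype=float) / 255.0
        mask = None
        if row.mask_path:
            mask = np.asarray(Image.open(root / row.mask_path)) > 127
        records.append(
            ImageRecord(
                image_id=row.image_id,
                pixels=pixels,
                label=int(row.label),
                mask=mask,
                split=row.split or None,
            )
        )
    return records
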