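"""Score-CAM attribution for the transformer, plus heatmap-mask concordance.

Score-CAM is gradient-free: each channel of the final-block patch-token map
is reshaped to the patch grid, min-max normalized, bilinearly upsampled to
the input resolution and used to mask the input image; the masked image is
re-forwarded and the change in the target class's softmax score relative to
an all-zero baseline image becomes that channel's weight.  The heatmap is
the rectified weighted sum of the normalized maps, min-max normalized to
[0, 1] (an all-zero weighted sum stays all-zero).

Concordance against a ground-truth lesion mask binarizes the heatmap at
``binarize_thresh`` and asks what fraction of the high-activation region
falls inside the mask; the verdict is concordant when that fraction reaches
``tau`` (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize

from .model import ModelWeights, forward_batch
from .pipeline import PatchGrid

__all__ = [
    "Heatmap",
    "ConcordanceResult",
    "token_activation_maps",
    "score_cam",
    "score_cam_model",
    "overlap_concordance",
    "overlay",
    "concordance_rate",
]


@dataclass
class Heatmap:
    """Attribution map in [0, 1] at input resolution."""

    values: np.ndarray
    target_class: int
    image_id: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


@dataclass
class ConcordanceResult:
    overlap_fraction: float
    concordant: bool
    binarize_thresh: float
    tau: float


def token_activation_maps(patch_tokens: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Reshape final patch tokens (n_patches, D) to D spatial maps (D, n, n).

    Channel c of the token matrix, read row-major over the patch grid, is
    map c.  The [CLS] token must already be excluded.
    """
    tokens = np.asarray(patch_tokens)
    n_patches, d = tokens.shape
    side = int(round(np.sqrt(n_patches)))
    if side * side != n_patches:
        raise ValueError(f"token count {n_patches} is not a perfect square")
    if n_patches != grid.n_patches:
        raise ValueError(f"token count {n_patches} does not match grid ({grid.n_patches})")
    return tokens.T.reshape(d, side, side)


def _minmax(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def score_cam(
    score_fn: Callable[[np.ndarray], np.ndarray],
    maps: np.ndarray,
    image: np.ndarray,
    target_class: int,
    top_k: int | None = 64,
    image_id: str = "",
) -> Heatmap:
    """Generic Score-CAM over arbitrary activation maps.

    ``score_fn`` maps a batch of images (B, H, W, 3) to target-class softmax
    scores (B,).  ``maps`` is (C, h, w) at any spatial resolution; each map is
    min-max normalized, upsampled to the image resolution, and used to mask
    the image.  Channel weights are masked-image score minus the score of an
    all-zero image; channels are optionally pre-selected as the ``top_k`` by
    spatial variance to bound the number of re-forward passes.
    """
    maps = np.asarray(maps, dtype=float)
    h, w = image.shape[:2]
    c = maps.shape[0]
    if top_k is not None and top_k > c:
        import warnings

        warnings.warn(f"top_k={top_k} exceeds {c} channels; using all channels")
        top_k = None
    if top_k is not None:
        order = np.argsort(maps.reshape(c, -1).var(axis=1))[::-1][:top_k]
        maps = maps[order]

    norm_maps = np.stack(
        [resize(_minmax(m), (h, w), order=1, mode="edge", anti_aliasing=False) for m in maps]
    )
    masked = norm_maps[..., None] * image[None]
    baseline = float(score_fn(np.zeros((1, h, w, 3)))[0])
    scores = score_fn(masked)
    weights = scores - baseline
    combined = np.tensordot(weights, norm_maps, axes=(0, 0))
    combined = np.maximum(combined, 0.0)
    return Heatmap(values=_minmax(combined), target_class=target_class, image_id=image_id)


def score_cam_model(
    model: ModelWeights,
    image: np.ndarray,
    target_class: int | None = None,
    top_k: int | None = 64,
    image_id: str = "",
    batch_size: int = 64,
) -> Heatmap:
    """Score-CAM for a trained model on one preprocessed image.

    Activation maps are the channels of the final-block patch tokens; the
    target class defaults to the model's predicted class.
    """
    from .model import predict  # local import keeps module load light

    cfg = model.config
    if target_class is None:
        target_class = predict(image, model).predicted_class

    _, _, tokens = forward_batch(image[None], model, train_mode=False, return_tokens=True)
    maps = token_activation_maps(tokens.data[0], cfg.grid)

    def score_fn(images: np.ndarray) -> np.ndarray:
        out = np.empty(len(images))
        for start in range(0, len(images), batch_size):
            chunk = images[start : start + batch_size]
            logits, _ = forward_batch(chunk, model, train_mode=False)
            out[start : start + len(chunk)] = logits.softmax().data[:, target_class]
        return out

    return score_cam(score_fn, maps, image, target_class, top_k=top_k, image_id=image_id)


def overlap_concordance(
    heatmap: Heatmap | np.ndarray,
    mask: np.ndarray,
    binarize_thresh: float = 0.5,
    tau: float = 0.5,
) -> ConcordanceResult:
    """Fraction of the high-activation region inside the lesion mask.

    A = {heatmap >= binarize_thresh}; overlap = |A intersect mask| / |A|
    (0 when A is empty); concordant iff overlap >= tau.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    mask = np.asarray(mask).astype(bool)
    if values.shape != mask.shape:
        raise ValueError(f"heatmap shape {values.shape} != mask shape {mask.shape}")
    active = values >= binarize_thresh
    n_active = int(active.sum())
    frac = float((active & mask).sum() / n_active) if n_active else 0.0
    return ConcordanceResult(
        overlap_fraction=frac,
        concordant=frac >= tau,
        binarize_thresh=binarize_thresh,
        tau=tau,
    )


def concordance_rate(
    model: ModelWeights,
    records: Sequence,
    top_k: int | None = 64,
    binarize_thresh: float = 0.5,
    tau: float = 0.5,
    shuffle_masks_seed: int | None = None,
) -> float:
    """Mean concordance over records that carry a lesion mask.

    With ``shuffle_masks_seed`` set, masks are randomly reassigned among the
    records (a permutation with no fixed point when possible), giving the
    chance-level baseline for the same heatmaps.
    """
    with_mask = [r for r in records if r.mask is not None and r.mask.any()]
    if not with_mask:
        raise ValueError("no records with non-empty masks")
    masks = [r.mask for r in with_mask]
    if shuffle_masks_seed is not None:
        rng = np.random.default_rng(shuffle_masks_seed)
        n = len(masks)
        perm = rng.permutation(n)
        if n > 1:
            for i in np.nonzero(perm == np.arange(n))[0]:
                j = (i + 1) % n
                perm[i], perm[j] = perm[j], perm[i]
        masks = [masks[i] for i in perm]
    hits = 0
    for rec, mask in zip(with_mask, masks):
        hm = score_cam_model(model, rec.pixels, target_class=rec.label, top_k=top_k)
        if overlap_concordance(hm, mask, binarize_thresh, tau).concordant:
            hits += 1
    return hits / len(with_mask)


def overlay(
    heatmap: Heatmap | np.ndarray,
    image: np.ndarray,
    colormap: str = "jet",
    alpha: float = 0.45,
) -> np.ndarray:
    """Alpha-blend the colorized heatmap over the image (warm = high).

    Output is (H, W, 3) in [0, 1] with the same spatial dims as the input.
    """
    import matplotlib

    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    if values.shape != image.shape[:2]:
        raise ValueError("heatmap and image spatial dims must match")
    colored = matplotlib.colormaps[colormap](values)[..., :3]
    out = (1.0 - alpha) * image + alpha * colored
    return np.clip(out, 0.0, 1.0)
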