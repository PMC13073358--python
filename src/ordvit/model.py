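"""Progression-aware vision transformer with dual categorical/continuous heads.

The network has three parts:

1. A pre-norm ViT encoder: the frame is cut into non-overlapping patches,
   each linearly projected to a D-dimensional token, a learnable [CLS] token
   is prepended, learnable positional encodings are added, and L transformer
   blocks (multi-head self-attention + GELU feed-forward, LayerNorm before
   each sublayer, residuals around each, dropout on attention weights and
   feed-forward outputs) produce a final [CLS] vector — the global lesion
   descriptor — plus the final patch tokens used for attribution.

2. A Sequential Feature Learner (SFL) that encodes the ordinal
   benign -> low-risk -> high-risk -> malignant axis: the [CLS] vector is
   replicated across four stage positions, combined additively with learned
   stage embeddings e_0..e_3, passed through two self-attention layers, then
   a per-stage feed-forward network (D -> hidden -> out with GELU), and the
   four stage outputs are averaged into one pooled vector.

3. Two parallel heads on the pooled vector: a 4-way linear + softmax
   classifier, and a linear + sigmoid regressor emitting a continuous
   malignancy risk score in [0, 1].

Ablation variants: ``no_progression`` attaches the heads directly to the
[CLS] vector; ``no_self_attention`` replaces each SFL attention sublayer with
a width-preserving fully connected layer with GELU, keeping the residual
structure, FFN and pooling unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from .pipeline import PatchGrid, patchify

__all__ = [
    "ModelConfig",
    "ModelWeights",
    "StagePrediction",
    "VARIANTS",
    "build_model",
    "embed_patches",
    "vit_encode",
    "sfl_forward",
    "forward_batch",
    "predict",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("full", "no_progression", "no_self_attention")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; use :meth:`tiny` or :meth:`base`."""

    image_size: int = 224
    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 12
    n_heads: int = 12
    ffn_dim: int = 3072
    dropout: float = 0.1
    n_stages: int = 4
    sfl_layers: int = 2
    sfl_heads: int = 12
    sfl_hidden: int = 1024
    sfl_out: int = 512
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.embed_dim % self.sfl_heads:
            raise ValueError("embed_dim must be divisible by sfl_heads")
        if self.image_size % self.patch_size:
            raise ValueError("patch_size must divide image_size")
        if self.n_stages != 4:
            raise ValueError("the ordinal axis has exactly 4 stages")

    @classmethod
    def base(cls) -> "ModelConfig":
        """ViT-B/16 geometry: 12 blocks, 12 heads, dim 768, FFN 3072."""
        return cls()

    @classmethod
    def tiny(cls) -> "ModelConfig":
        """Desk-scale preset: 64-px input, 8-px patches, dim 64, 2 blocks."""
        return cls(
            image_size=64,
            patch_size=8,
            embed_dim=64,
            depth=2,
            n_heads=4,
            ffn_dim=128,
            sfl_heads=4,
            sfl_hidden=96,
            sfl_out=48,
        )

    @property
    def grid(self) -> PatchGrid:
        return PatchGrid(self.image_size, self.patch_size)

    @property
    def n_patches(self) -> int:
        return self.grid.n_patches

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * 3


@dataclass
class StagePrediction:
    """Per-image output: 4-class probabilities plus a continuous risk score."""

    class_probs: np.ndarray
    risk_score: float
    logits: np.ndarray

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.class_probs))


class ModelWeights:
    """Named parameter bundle for one model variant."""

    def __init__(self, config: ModelConfig, variant: str, params: dict[str, Tensor]):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.config = config
        self.variant = variant
        self.params = params

    def __getitem__(self, name: str) -> Tensor:
        return self.params[name]

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def copy_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in arrays.items():
            self.params[k].data = v.copy()

    @property
    def pooled_dim(self) -> int:
        return self.config.embed_dim if self.variant == "no_progression" else self.config.sfl_out


def _trunc_normal(rng: np.random.Generator, shape: tuple[int, ...], sd: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, sd, size=shape)
    return np.clip(x, -2.0 * sd, 2.0 * sd)


def _init_attn(params: dict, prefix: str, dim: int, rng: np.random.Generator) -> None:
    for name in ("q", "k", "v", "o"):
        params[f"{prefix}.w{name}"] = Tensor(_trunc_normal(rng, (dim, dim)))
        params[f"{prefix}.b{name}"] = Tensor(np.zeros(dim))


def _init_ln(params: dict, prefix: str, dim: int) -> None:
    params[f"{prefix}_g"] = Tensor(np.ones(dim))
    params[f"{prefix}_b"] = Tensor(np.zeros(dim))


def build_model(config: ModelConfig, variant: str = "full", seed: int = 0) -> ModelWeights:
    """Create a seeded weight bundle for the requested variant.

    Linear weights and all learned embeddings use a truncated normal
    (sd 0.02, clipped at two standard deviations); biases and LayerNorm
    offsets start at zero, LayerNorm gains at one.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rng = np.random.default_rng(seed)
    D = config.embed_dim
    p: dict[str, Tensor] = {}

    p["patch_w"] = Tensor(_trunc_normal(rng, (config.patch_dim, D)))
    p["patch_b"] = Tensor(np.zeros(D))
    p["cls"] = Tensor(_trunc_normal(rng, (1, D)))
    p["pos"] = Tensor(_trunc_normal(rng, (config.n_patches + 1, D)))

    for i in range(config.depth):
        _init_ln(p, f"blk{i}.ln1", D)
        _init_attn(p, f"blk{i}.attn", D, rng)
        _init_ln(p, f"blk{i}.ln2", D)
        p[f"blk{i}.ffn_w1"] = Tensor(_trunc_normal(rng, (D, config.ffn_dim)))
        p[f"blk{i}.ffn_b1"] = Tensor(np.zeros(config.ffn_dim))
        p[f"blk{i}.ffn_w2"] = Tensor(_trunc_normal(rng, (config.ffn_dim, D)))
        p[f"blk{i}.ffn_b2"] = Tensor(np.zeros(D))
    _init_ln(p, "final_ln", D)

    if variant == "no_progression":
        head_dim = D
    else:
        p["stage_emb"] = Tensor(_trunc_normal(rng, (config.n_stages, D)))
        for i in range(config.sfl_layers):
            if variant == "full":
                _init_ln(p, f"sfl{i}.ln1", D)
                _init_attn(p, f"sfl{i}.attn", D, rng)
            else:  # no_self_attention: width-preserving FC in place of attention
                _init_ln(p, f"sfl{i}.ln1", D)
                p[f"sfl{i}.fc_w"] = Tensor(_trunc_normal(rng, (D, D)))
                p[f"sfl{i}.fc_b"] = Tensor(np.zeros(D))
        p["sfl_ffn_w1"] = Tensor(_trunc_normal(rng, (D, config.sfl_hidden)))
        p["sfl_ffn_b1"] = Tensor(np.zeros(config.sfl_hidden))
        p["sfl_ffn_w2"] = Tensor(_trunc_normal(rng, (config.sfl_hidden, config.sfl_out)))
        p["sfl_ffn_b2"] = Tensor(np.zeros(config.sfl_out))
        head_dim = config.sfl_out

    p["head_cls_w"] = Tensor(_trunc_normal(rng, (head_dim, config.n_classes)))
    p["head_cls_b"] = Tensor(np.zeros(config.n_classes))
    p["head_risk_w"] = Tensor(_trunc_normal(rng, (head_dim, 1)))
    p["head_risk_b"] = Tensor(np.zeros(1))
    return ModelWeights(config, variant, p)


def parameter_count(model: ModelWeights) -> int:
    return int(sum(t.data.size for t in model.params.values()))


# --------------------------------------------------------------------- forward


def _dropout(x: Tensor, rate: float, train_mode: bool, rng: np.random.Generator | None) -> Tensor:
    if not train_mode or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("train_mode dropout requires an rng")
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * keep


def _attention(
    x: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    n_heads: int,
    dropout: float,
    train_mode: bool,
    rng: np.random.Generator | None,
) -> Tensor:
    """Multi-head self-attention over (batch, tokens, dim); dropout on weights."""
    B, T, D = x.shape
    dh = D // n_heads

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)

    q = split_heads(x @ params[f"{prefix}.wq"] + params[f"{prefix}.bq"])
    k = split_heads(x @ params[f"{prefix}.wk"] + params[f"{prefix}.bk"])
    v = split_heads(x @ params[f"{prefix}.wv"] + params[f"{prefix}.bv"])
    att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    att = att.softmax()
    att = _dropout(att, dropout, train_mode, rng)
    out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
    return out @ params[f"{prefix}.wo"] + params[f"{prefix}.bo"]


def _ffn(x: Tensor, params: dict[str, Tensor], w1: str, b1: str, w2: str, b2: str) -> Tensor:
    return (x @ params[w1] + params[b1]).gelu() @ params[w2] + params[b2]


def embed_patches_batch(patches: np.ndarray, model: ModelWeights) -> Tensor:
    """(B, n_patches, patch_dim) -> (B, n_patches + 1, D) with [CLS] at index 0."""
    cfg = model.config
    if patches.shape[-1] != cfg.patch_dim:
        raise ValueError(
            f"patch vectors have length {patches.shape[-1]}, expected {cfg.patch_dim}"
        )
    B = patches.shape[0]
    tok = Tensor(patches) @ model["patch_w"] + model["patch_b"]
    cls = Tensor(np.ones((B, 1, 1))) * model["cls"].reshape(1, 1, cfg.embed_dim)
    tokens = concat([cls, tok], axis=1)
    return tokens + model["pos"].reshape(1, cfg.n_patches + 1, cfg.embed_dim)


def embed_patches(patches: np.ndarray, model: ModelWeights) -> Tensor:
    """Single-image patch embedding: (n_patches, patch_dim) -> (n_patches+1, D)."""
    out = embed_patches_batch(patches[None], model)
    return out.reshape(out.shape[1], out.shape[2])


def vit_encode(
    tokens: Tensor,
    model: ModelWeights,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Run the L pre-norm blocks; return (CLS vectors (B, D), patch tokens (B, N, D)).

    Both outputs come from the final LayerNorm.  Raises FloatingPointError
    naming the block if activations go non-finite.
    """
    cfg = model.config
    x = tokens if tokens.ndim == 3 else tokens.reshape(1, *tokens.shape)
    for i in range(cfg.depth):
        h = x.layer_norm(model[f"blk{i}.ln1_g"], model[f"blk{i}.ln1_b"])
        x = x + _attention(h, model.params, f"blk{i}.attn", cfg.n_heads, cfg.dropout, train_mode, rng)
        h = x.layer_norm(model[f"blk{i}.ln2_g"], model[f"blk{i}.ln2_b"])
        x = x + _dropout(
            _ffn(h, model.params, f"blk{i}.ffn_w1", f"blk{i}.ffn_b1", f"blk{i}.ffn_w2", f"blk{i}.ffn_b2"),
            cfg.dropout,
            train_mode,
            rng,
        )
        if not np.isfinite(x.data).all():
            raise FloatingPointError(f"non-finite activations after encoder block {i}")
    x = x.layer_norm(model["final_ln_g"], model["final_ln_b"])
    return x[:, 0, :], x[:, 1:, :]


def sfl_forward(
    cls_embedding: Tensor,
    model: ModelWeights,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Ordinal-stage module: (B, D) -> pooled (B, sfl_out).

    Builds stage tokens s_k = CLS + e_k for the four ordinal stages, runs the
    stage-mixing layers, applies the per-stage FFN, and averages over stages.
    """
    cfg = model.config
    B, D = cls_embedding.shape
    x = cls_embedding.reshape(B, 1, D) + model["stage_emb"].reshape(1, cfg.n_stages, D)
    for i in range(cfg.sfl_layers):
        h = x.layer_norm(model[f"sfl{i}.ln1_g"], model[f"sfl{i}.ln1_b"])
        if model.variant == "no_self_attention":
            x = x + (h @ model[f"sfl{i}.fc_w"] + model[f"sfl{i}.fc_b"]).gelu()
        else:
            x = x + _attention(h, model.params, f"sfl{i}.attn", cfg.sfl_heads, cfg.dropout, train_mode, rng)
    x = _ffn(x, model.params, "sfl_ffn_w1", "sfl_ffn_b1", "sfl_ffn_w2", "sfl_ffn_b2")
    x = _dropout(x, cfg.dropout, train_mode, rng)
    return x.mean(axis=1)


def forward_batch(
    images: np.ndarray,
    model: ModelWeights,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_tokens: bool = False,
):
    """Full differentiable forward pass on a batch of preprocessed images.

    Returns (logits (B, 4), risk (B,)) Tensors, plus the final patch tokens
    when ``return_tokens`` is set.
    """
    cfg = model.config
    patches = np.stack([patchify(img, cfg.patch_size) for img in np.asarray(images)])
    tokens = embed_patches_batch(patches, model)
    cls_vec, patch_tokens = vit_encode(tokens, model, train_mode, rng)
    if model.variant == "no_progression":
        pooled = cls_vec
    else:
        pooled = sfl_forward(cls_vec, model, train_mode, rng)
    logits = pooled @ model["head_cls_w"] + model["head_cls_b"]
    risk = (pooled @ model["head_risk_w"] + model["head_risk_b"]).sigmoid()
    risk = risk.reshape(risk.shape[0])
    if return_tokens:
        return logits, risk, patch_tokens
    return logits, risk


def predict(image: np.ndarray, model: ModelWeights) -> StagePrediction:
    """Eval-mode prediction for one preprocessed image (deterministic)."""
    logits, risk = forward_batch(image[None], model, train_mode=False)
    probs = logits.softmax().data[0]
    return StagePrediction(class_probs=probs, risk_score=float(risk.data[0]), logits=logits.data[0])


def predict_batch(images: np.ndarray, model: ModelWeights) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode class probabilities (B, 4) and risk scores (B,) as arrays."""
    logits, risk = forward_batch(images, model, train_mode=False)
    return logits.softmax().data, risk.data


# ------------------------------------------------------------------ checkpoints


def save_checkpoint(model: ModelWeights, path: str | Path, train_seed: int | None = None) -> None:
    """Serialize weights + config + variant (+ training seed) to one .npz file."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "variant": model.variant,
        "train_seed": train_seed,
    }
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ModelWeights:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        cfg = ModelConfig(**meta["config"])
        model = build_model(cfg, meta["variant"], seed=0)
        for k in model.params:
            model.params[k].data = npz[k].copy()
    return model
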