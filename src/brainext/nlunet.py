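"""Nonlocal attention U-Net backbone for slice-wise brain extraction.

A five-level (configurable) encoder/decoder. Each block is two 3×3
convolutions, each followed by batch normalization and an ELU; encoder
levels are separated by 2×2 stride-2 max pooling and the first level
produces ``base_channels`` feature maps, doubling at every level below.
The deepest level (the bottleneck) carries an embedded-Gaussian nonlocal
attention block so distant positions can inform one another. Decoder
levels mirror the encoder, upsampling with 2×2 stride-2 transposed
convolutions and concatenating the encoder skip connection. A final
convolution (3×3 by default; 1×1 switchable via ``head_kernel``) maps the
first-level features to one channel, and a sigmoid yields the per-pixel
brain probability.

Spatial dropout sits at the bottleneck and the two deepest decoder
levels; keeping it active at inference yields the stochastic forward
passes used for Monte Carlo uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np

from .errors import ConfigurationError, DimensionError
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    ELU,
    MaxPool2x2,
    NonLocalBlock,
    Sigmoid,
    SpatialDropout2d,
)

__all__ = ["ModelConfig", "NLUNet", "build_model", "forward", "forward_mc",
           "get_attention_map", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 5
    base_channels: int = 16
    in_plane_size: int = 256
    dropout_rate: float = 0.2
    dropout_sites: str = "both"  # bottleneck | decoder | both
    attention: bool = True
    head_kernel: int = 3  # 3 (default reading) or 1
    dropout_in_training: bool = False  # inference-only dropout by default
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.in_plane_size % (2 ** self.depth) != 0:
            raise ConfigurationError(
                f"in_plane_size {self.in_plane_size} not divisible by "
                f"2^depth = {2 ** self.depth}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.dropout_sites not in ("bottleneck", "decoder", "both"):
            raise ConfigurationError(f"unknown dropout_sites {self.dropout_sites!r}")
        if self.head_kernel not in (1, 3):
            raise ConfigurationError("head_kernel must be 1 or 3")

    @property
    def channel_widths(self) -> tuple:
        return tuple(self.base_channels * 2 ** k for k in range(self.depth))

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class _ConvBlock:
    """[conv 3×3 → BN → ELU] × 2."""

    def __init__(self, in_ch, out_ch, rng, dtype, name):
        self.layers = [
            Conv2d(in_ch, out_ch, 3, rng, dtype, f"{name}.conv1"),
            BatchNorm2d(out_ch, dtype=dtype, name=f"{name}.bn1"),
            ELU(),
            Conv2d(out_ch, out_ch, 3, rng, dtype, f"{name}.conv2"),
            BatchNorm2d(out_ch, dtype=dtype, name=f"{name}.bn2"),
            ELU(),
        ]

    def forward(self, x, mode, rng):
        for layer in self.layers:
            x = layer.forward(x, mode, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def bn_layers(self):
        return [l for l in self.layers if isinstance(l, BatchNorm2d)]


class NLUNet:
    """Segmentation network; see module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = cfg.np_dtype
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channel_widths

        self.enc_blocks: List[_ConvBlock] = []
        self.pools: List[MaxPool2x2] = []
        in_ch = 1
        for k in range(cfg.depth):
            self.enc_blocks.append(_ConvBlock(in_ch, ch[k], rng, dtype, f"enc{k}"))
            in_ch = ch[k]
            if k < cfg.depth - 1:
                self.pools.append(MaxPool2x2())

        self.attention = NonLocalBlock(ch[-1], rng, dtype) if cfg.attention else None
        self.bottleneck_dropout = (
            SpatialDropout2d(cfg.dropout_rate, cfg.dropout_in_training)
            if cfg.dropout_sites in ("bottleneck", "both")
            else None
        )

        self.ups: List[ConvTranspose2x2] = []
        self.dec_blocks: List[_ConvBlock] = []
        self.dec_dropouts: List[Optional[SpatialDropout2d]] = []
        deep_decoder_levels = {cfg.depth - 2, cfg.depth - 3}
        for k in range(cfg.depth - 2, -1, -1):
            self.ups.append(ConvTranspose2x2(ch[k + 1], ch[k], rng, dtype, f"up{k}"))
            self.dec_blocks.append(_ConvBlock(2 * ch[k], ch[k], rng, dtype, f"dec{k}"))
            use_do = (
                cfg.dropout_sites in ("decoder", "both")
                and k in deep_decoder_levels
                and k >= 0
            )
            self.dec_dropouts.append(
                SpatialDropout2d(cfg.dropout_rate, cfg.dropout_in_training)
                if use_do else None)

        self.head = Conv2d(ch[0], 1, cfg.head_kernel, rng, dtype, "head")
        # brain tissue is a minority class (~10% of a head slice); starting
        # the head at the prior logit instead of 0.5 keeps the initial
        # false-positive mass small, which the Dice loss punishes slowly
        self.head.bias.data[:] = np.log(0.1 / 0.9)
        self.sigmoid = Sigmoid()
        self._skip_cache = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        out = []
        for blk in self.enc_blocks:
            out += blk.params()
        if self.attention is not None:
            out += self.attention.params()
        for up in self.ups:
            out += up.params()
        for blk in self.dec_blocks:
            out += blk.params()
        out += self.head.params()
        return out

    def bn_layers(self):
        out = []
        for blk in self.enc_blocks + self.dec_blocks:
            out += blk.bn_layers()
        return out

    def param_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def freeze_bn_stats(self, frozen: bool = True) -> None:
        """Freeze/unfreeze normalization statistics (scale/shift still train).

        Used for target-domain fine-tuning, where re-estimating running
        statistics from a handful of volumes is noisier than keeping the
        source (or AdaBN-transferred) statistics.
        """
        for bn in self.bn_layers():
            bn.stats_frozen = frozen

    def state_dict(self) -> dict:
        state = {p.name: p.data.copy() for p in self.parameters()}
        for i, bn in enumerate(self.bn_layers()):
            state[f"{bn.name}#{i}.running_mean"] = bn.running_mean.copy()
            state[f"{bn.name}#{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ConfigurationError("checkpoint does not match model config")
        for p in self.parameters():
            p.data = np.array(state[p.name], dtype=p.data.dtype)
        for i, bn in enumerate(self.bn_layers()):
            bn.running_mean = np.array(state[f"{bn.name}#{i}.running_mean"],
                                       dtype=bn.running_mean.dtype)
            bn.running_var = np.array(state[f"{bn.name}#{i}.running_var"],
                                      dtype=bn.running_var.dtype)

    def copy(self) -> "NLUNet":
        clone = NLUNet(self.cfg)
        clone.load_state_dict(self.state_dict())
        return clone

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=self.cfg.np_dtype)
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise DimensionError("expected (batch, 1, size, size) slices")
        s = self.cfg.in_plane_size
        if x.shape[2] != s or x.shape[3] != s:
            raise DimensionError(
                f"in-plane size {x.shape[2]}×{x.shape[3]} != configured {s}×{s}"
            )
        return x

    def forward(self, x, mode: str = "eval", rng: Optional[np.random.Generator] = None):
        """Run the network; returns per-pixel probabilities in (0, 1)."""
        x = self._check_input(x)
        skips = []
        h = x
        for k, blk in enumerate(self.enc_blocks):
            h = blk.forward(h, mode, rng)
            if k < self.cfg.depth - 1:
                skips.append(h)
                h = self.pools[k].forward(h, mode, rng)
        if self.attention is not None:
            h = self.attention.forward(h, mode, rng)
        if self.bottleneck_dropout is not None:
            h = self.bottleneck_dropout.forward(h, mode, rng)
        self._skip_cache = skips
        for i, (up, blk) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h, mode, rng)
            skip = skips[-(i + 1)]
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, mode, rng)
            if self.dec_dropouts[i] is not None:
                h = self.dec_dropouts[i].forward(h, mode, rng)
        h = self.head.forward(h, mode, rng)
        return self.sigmoid.forward(h, mode, rng)

    def backward(self, dprob):
        """Backpropagate a gradient w.r.t. the output probabilities."""
        dy = self.sigmoid.backward(dprob)
        dy = self.head.backward(dy)
        skip_grads = [None] * len(self.enc_blocks)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            if self.dec_dropouts[i] is not None:
                dy = self.dec_dropouts[i].backward(dy)
            dy = self.dec_blocks[i].backward(dy)
            n_skip = self._skip_cache[-(i + 1)].shape[1]
            dskip, dup = dy[:, :n_skip], dy[:, n_skip:]
            skip_grads[len(self.enc_blocks) - 2 - i] = dskip
            dy = self.ups[i].backward(np.ascontiguousarray(dup))
        if self.bottleneck_dropout is not None:
            dy = self.bottleneck_dropout.backward(dy)
        if self.attention is not None:
            dy = self.attention.backward(dy)
        for k in range(len(self.enc_blocks) - 1, -1, -1):
            if k < self.cfg.depth - 1:
                dy = self.pools[k].backward(dy)
                dy = dy + skip_grads[k]
            dy = self.enc_blocks[k].backward(dy)
        self._skip_cache = None
        return dy


def build_model(cfg: ModelConfig) -> NLUNet:
    """Construct a network with deterministic initialization under ``cfg.seed``."""
    return NLUNet(cfg)


def forward(model: NLUNet, slices, mode: str = "eval",
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Deterministic inference (dropout inactive); returns (n, size, size)."""
    return model.forward(slices, mode=mode, rng=rng)[:, 0]


def forward_mc(model: NLUNet, slices, T: int = 10, seed: int = 0,
               batch_size: int = 16) -> List[np.ndarray]:
    """T stochastic forward passes with dropout kept active.

    Each pass uses an independent child stream of ``seed``, so the full
    sample list is reproducible under a fixed master seed.
    """
    if T < 2:
        raise ConfigurationError("Monte Carlo sampling requires T >= 2")
    if model.cfg.dropout_rate == 0:
        raise ConfigurationError(
            "dropout_rate is 0: Monte Carlo dropout sampling is meaningless"
        )
    slices = np.asarray(slices)
    children = np.random.SeedSequence(seed).spawn(T)
    out = []
    for t in range(T):
        rng = np.random.default_rng(children[t])
        parts = [
            model.forward(slices[i:i + batch_size], mode="mc", rng=rng)[:, 0]
            for i in range(0, slices.shape[0], batch_size)
        ]
        out.append(np.concatenate(parts, axis=0))
    return out


def get_attention_map(model: NLUNet, slices) -> np.ndarray:
    """Per-slice attention saliency in [0, 1].

    Saliency of a position is the affinity mass it receives from all
    query positions, upsampled from the bottleneck grid to the slice size
    and min-max normalized per slice.
    """
    from skimage.transform import resize as _resize

    if model.attention is None:
        raise ConfigurationError("model built without attention")
    model.forward(slices, mode="eval")
    att = model.attention.last_affinity  # (N, P, P)
    n = att.shape[0]
    p = att.shape[1]
    side = int(round(np.sqrt(p)))
    received = att.sum(axis=1).reshape(n, side, side)
    size = model.cfg.in_plane_size
    maps = np.stack([
        _resize(r, (size, size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
        for r in received
    ])
    lo = maps.min(axis=(1, 2), keepdims=True)
    hi = maps.max(axis=(1, 2), keepdims=True)
    return (maps - lo) / np.where(hi - lo > 0, hi - lo, 1.0)


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(model: NLUNet, path) -> None:
    """Write parameters, BN statistics and config to an .npz file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(str(path), **state)


def load_checkpoint(path) -> NLUNet:
    with np.load(str(path)) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = NLUNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
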