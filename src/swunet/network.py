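"""SW-UNet assembly: CNN encoder, feature expansion into the transformer
bottleneck, feature contraction, CNN decoder with skip connections, and
parameter / FLOP accounting.

The encoder is a plain convolutional contracting path (two 3x3 convolutions
per level, stride-2 convolution downsampling, widths doubling from
``base_width``).  At the bottom, a convolution expands the channel count to
the token dimension ``d`` and the spatial axes are flattened into the token
sequence consumed by the Sliding Window Transformer Block.  Two convolutions
contract the transformer output back to the encoder's bottom shape, and a
transposed-convolution decoder with concatenation skip connections restores
full resolution, ending in a 1x1 convolution to per-pixel class logits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .model_core import (
    DimensionError,
    FeatureGrid,
    SlidingWindowTransformerBlock,
    TokenSequence,
    attention_cost,
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of SW-UNet.

    Defaults reproduce the reference operating point: 1x128x128 input, 16
    initial convolution kernels, two downsampling stages (token grid 32x32),
    token dimension 256, query/key widening rate 2, 4 attention heads, 4x4
    windows shifted by 2.  ``use_sliding_window=False`` replaces the shifted
    masked attention with a second unshifted one (ablation arm).
    """

    in_channels: int = 1
    input_side: int = 128
    base_width: int = 16
    encoder_depth: int = 2
    token_dim: int = 256
    widening_rate: int = 2
    n_heads: int = 4
    window_side: int = 4
    shift: int = 2
    n_classes: int = 2
    use_sliding_window: bool = True

    def __post_init__(self):
        if not 1 <= self.encoder_depth <= 3:
            raise ValueError(f"encoder_depth must be in 1..3, got {self.encoder_depth}")
        if self.input_side % (2 ** self.encoder_depth):
            raise DimensionError(
                f"input_side {self.input_side} not divisible by 2^{self.encoder_depth}"
            )
        if self.grid_side % self.window_side:
            raise DimensionError(
                f"token grid side {self.grid_side} not divisible by window {self.window_side}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def grid_side(self) -> int:
        return self.input_side // (2 ** self.encoder_depth)

    @property
    def bottom_channels(self) -> int:
        return self.base_width * 2 ** self.encoder_depth

    @property
    def level_widths(self) -> tuple:
        return tuple(self.base_width * 2 ** i for i in range(self.encoder_depth + 1))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class _ConvBlock(nn.Module):
    """Two consecutive 3x3 convolutions with ReLU."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.c1 = nn.Conv2d(c_in, c_out, 3, rng, padding=1)
        self.c2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1)

    def forward(self, x):
        return ad.relu(self.c2(ad.relu(self.c1(x))))


class SWUNet(nn.Module):
    """The complete segmentation network (batched NCHW tensors)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.level_widths

        self.stem = _ConvBlock(cfg.in_channels, widths[0], rng)
        downs, blocks = [], []
        for lvl in range(1, cfg.encoder_depth + 1):
            downs.append(nn.Conv2d(widths[lvl - 1], widths[lvl], 3, rng, stride=2, padding=1))
            blocks.append(_ConvBlock(widths[lvl], widths[lvl], rng))
        self.downs = nn.ModuleList(downs)
        self.blocks = nn.ModuleList(blocks)

        self.expand_conv = nn.Conv2d(cfg.bottom_channels, cfg.token_dim, 3, rng, padding=1)
        self.swtb = SlidingWindowTransformerBlock(
            cfg.token_dim, cfg.grid_side, cfg.grid_side, cfg.window_side, cfg.shift,
            cfg.widening_rate, cfg.n_heads, cfg.use_sliding_window, rng,
        )
        self.contract1 = nn.Conv2d(cfg.token_dim, cfg.bottom_channels, 3, rng, padding=1)
        self.contract2 = nn.Conv2d(cfg.bottom_channels, cfg.bottom_channels, 3, rng, padding=1)

        ups, dec_blocks = [], []
        for lvl in range(cfg.encoder_depth, 0, -1):
            ups.append(nn.ConvTranspose2d(widths[lvl], widths[lvl - 1], rng))
            dec_blocks.append(_ConvBlock(2 * widths[lvl - 1], widths[lvl - 1], rng))
        self.ups = nn.ModuleList(ups)
        self.dec_blocks = nn.ModuleList(dec_blocks)
        self.head = nn.Conv2d(widths[0], cfg.n_classes, 1, rng)

    # ------------------------------------------------------------------
    def encode(self, x: Tensor):
        """(B, C, S, S) -> (bottom (B, C_b, S/2^depth, ..), skip list)."""
        cfg = self.cfg
        if x.shape[2] != cfg.input_side or x.shape[3] != cfg.input_side:
            raise DimensionError(
                f"expected {cfg.input_side}x{cfg.input_side} input, got {x.shape[2]}x{x.shape[3]}"
            )
        h = self.stem(x)
        skips = [h]
        for down, block in zip(self.downs, self.blocks):
            h = block(down(h))
            skips.append(h)
        bottom = skips.pop()
        return bottom, skips

    def expand_features(self, bottom: Tensor) -> Tensor:
        """(B, C_b, G, G) -> token sequence (B, N, d), row-major flattening."""
        if bottom.shape[1] != self.cfg.bottom_channels:
            raise DimensionError(
                f"bottom has {bottom.shape[1]} channels, expected {self.cfg.bottom_channels}"
            )
        z = self.expand_conv(bottom)  # (B, d, G, G)
        b, d = z.shape[0], z.shape[1]
        return z.reshape(b, d, self.cfg.grid_side ** 2).transpose(0, 2, 1)

    def contract_features(self, z: Tensor) -> Tensor:
        """(B, N, d) -> (B, C_b, G, G), matching the encoder bottom shape."""
        b, n, d = z.shape
        g = int(round(np.sqrt(n)))
        if g * g != n:
            raise DimensionError(f"token count {n} is not a perfect square")
        x = z.transpose(0, 2, 1).reshape(b, d, g, g)
        return ad.relu(self.contract2(ad.relu(self.contract1(x))))

    def decode(self, bottleneck: Tensor, skips: list) -> Tensor:
        """(B, C_b, G, G) + skips -> logits (B, n_classes, S, S)."""
        if len(skips) != len(self.ups):
            raise DimensionError(f"expected {len(self.ups)} skip levels, got {len(skips)}")
        h = bottleneck
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up(h)
            if h.shape[2] != skip.shape[2]:
                raise DimensionError(
                    f"decoder level size {h.shape[2]} != skip size {skip.shape[2]}"
                )
            h = block(ad.concatenate([h, skip], axis=1))
        return self.head(h)

    def forward(self, x: Tensor) -> Tensor:
        bottom, skips = self.encode(x)
        z0 = self.expand_features(bottom)
        z2 = self.swtb(z0)
        bottleneck = self.contract_features(z2)
        return self.decode(bottleneck, skips)

    # spec-level convenience on single unbatched grids ------------------
    def encode_grid(self, image: FeatureGrid):
        with ad.no_grad():
            bottom, skips = self.encode(Tensor(image.values[None]))
        return (FeatureGrid(bottom.data[0]), [FeatureGrid(s.data[0]) for s in skips])

    def expand_grid(self, bottom: FeatureGrid) -> TokenSequence:
        with ad.no_grad():
            z = self.expand_features(Tensor(bottom.values[None]))
        return TokenSequence(z.data[0].T, self.cfg.grid_side, self.cfg.grid_side, "z0")

    def contract_sequence(self, z: TokenSequence) -> FeatureGrid:
        with ad.no_grad():
            x = self.contract_features(Tensor(z.values.T[None]))
        return FeatureGrid(x.data[0])

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        """(B, S, S) or (B, 1, S, S) -> (B, n_classes, S, S), no gradient graph."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[:, None]
        with ad.no_grad():
            return self.forward(Tensor(images)).data


def count_parameters(cfg: ModelConfig, model: SWUNet | None = None) -> int:
    """Exact count of trainable scalars in the model built from ``cfg``."""
    if model is None:
        model = SWUNet(cfg)
    return model.n_parameters()


def estimate_flops(cfg: ModelConfig) -> dict:
    """Analytic multiply-accumulate count for one forward pass (batch 1).

    Convolutions contribute ``k^2 C_in C_out H W``; the windowed/global
    attention stages are taken from :func:`swunet.model_core.attention_cost`
    evaluated at the bottleneck grid; feed-forward sublayers contribute their
    two affine maps.  Returned per stage plus ``total``.
    """
    s = cfg.input_side
    widths = cfg.level_widths
    g, d = cfg.grid_side, cfg.token_dim
    n = g * g

    def conv(cin, cout, hw, k=3):
        return k * k * cin * cout * hw * hw

    enc = conv(cfg.in_channels, widths[0], s) + conv(widths[0], widths[0], s)
    side = s
    for lvl in range(1, cfg.encoder_depth + 1):
        side //= 2
        enc += conv(widths[lvl - 1], widths[lvl], side)  # stride-2 down
        enc += 2 * conv(widths[lvl], widths[lvl], side)

    expand = conv(cfg.bottom_channels, d, g)
    cost_w, cost_sw = attention_cost(g, g, d, cfg.window_side)
    # both windowed attention layers compute within M x M windows; widened
    # Q/K projections add (E-1) * 2 N d^2 on top of the 4 N d^2 in the formula
    widen_extra = (cfg.widening_rate - 1) * 2 * n * d * d
    attn = 2 * (cost_sw + widen_extra)
    ffn = 2 * (2 * n * d * 4 * d)
    global_attn = cost_w
    contract = conv(d, cfg.bottom_channels, g) + conv(cfg.bottom_channels, cfg.bottom_channels, g)

    dec = 0
    side = g
    for lvl in range(cfg.encoder_depth, 0, -1):
        side *= 2
        dec += conv(widths[lvl], widths[lvl - 1], side)  # transposed conv
        dec += conv(2 * widths[lvl - 1], widths[lvl - 1], side) + conv(
            widths[lvl - 1], widths[lvl - 1], side
        )
    head = conv(widths[0], cfg.n_classes, s, k=1)

    report = {
        "encoder": enc,
        "feature_expansion": expand,
        "attention_w_msa": cost_sw + widen_extra,
        "attention_sw_msa": cost_sw + widen_extra,
        "attention_global": global_attn,
        "ffn": ffn,
        "feature_contraction": contract,
        "decoder": dec,
        "head": head,
        "cost_w_msa": cost_w,
        "cost_sw_msa": cost_sw,
    }
    report["total"] = (
        enc + expand + attn + ffn + global_attn + contract + dec + head
    )
    return report
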