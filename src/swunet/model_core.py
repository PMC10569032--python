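"""Sliding Window Transformer Block (SWTB) primitives.

This module implements the attention machinery used at the U-Net bottleneck:

* partitioning a feature grid into non-overlapping ``M x M`` token windows,
* the cyclic shift that displaces windows by half a window so successive
  attention layers mix information across window borders,
* the additive masks that stop wrapped-around tokens (brought together only
  by the cyclic shift) from attending to tokens they were never adjacent to,
* widened windowed multi-head self-attention, in which the query/key hidden
  dimension is enlarged to ``d_m = E * d`` while the value dimension stays
  ``d``, with a learnable relative position bias ``B`` per head,
* the full transformer block (W-MSA, FFN, SW-MSA, FFN, each pre-layer-normed
  with residuals, followed by one global self-attention layer), and
* closed-form operation counts for global versus windowed attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

#: additive mask value that zeroes an attention weight after softmax while
#: remaining finite (gradient-safe)
MASK_VALUE = -1e9


class DimensionError(ValueError):
    """Raised when array shapes violate a structural precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureGrid:
    """Dense spatial feature array indexed ``(channel, row, col)``."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionError(f"FeatureGrid expects (C, H, W), got {self.values.shape}")
        if min(self.values.shape) < 1:
            raise DimensionError(f"degenerate grid shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureGrid values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]


@dataclass
class TokenSequence:
    """Token matrix ``(d x N)`` flattened row-major from a spatial grid."""

    values: np.ndarray
    grid_height: int
    grid_width: int
    stage_tag: str = "z0"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DimensionError(f"TokenSequence expects (d, N), got {self.values.shape}")
        if self.values.shape[1] != self.grid_height * self.grid_width:
            raise DimensionError(
                f"n_tokens {self.values.shape[1]} != grid {self.grid_height}x{self.grid_width}"
            )

    @property
    def token_dim(self) -> int:
        return self.values.shape[0]

    @property
    def n_tokens(self) -> int:
        return self.values.shape[1]

    def to_grid(self) -> FeatureGrid:
        d = self.token_dim
        return FeatureGrid(self.values.reshape(d, self.grid_height, self.grid_width))

    @classmethod
    def from_grid(cls, grid: FeatureGrid, stage_tag: str = "z0") -> "TokenSequence":
        c, h, w = grid.values.shape
        return cls(grid.values.reshape(c, h * w), h, w, stage_tag)


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: side ``M``, shift ``s`` and the token-grid size."""

    window_side: int
    shift: int
    grid_height: int
    grid_width: int

    def __post_init__(self):
        m = self.window_side
        if m < 1:
            raise ValueError(f"window_side must be positive, got {m}")
        if self.grid_height % m or self.grid_width % m:
            raise DimensionError(
                f"window_side {m} must divide grid {self.grid_height}x{self.grid_width}"
            )
        if not 0 <= self.shift < m:
            raise ValueError(f"shift must satisfy 0 <= s < {m}, got {self.shift}")

    @property
    def n_windows(self) -> int:
        return (self.grid_height // self.window_side) * (self.grid_width // self.window_side)


@dataclass
class MaskSet:
    """Additive attention masks, one ``(M^2, M^2)`` array per window."""

    per_window_mask: dict
    n_distinct_patterns: int


@dataclass
class AttentionParams:
    """Weights of one widened windowed attention layer.

    ``Wq, Wk`` map ``d -> d_m = E * d``; ``Wv`` maps ``d -> d``; ``B`` is a
    free learnable ``(n_heads, M^2, M^2)`` relative position bias.
    """

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    B: np.ndarray
    n_heads: int = 4
    scale: float = field(default=0.0)

    def __post_init__(self):
        d, dm = self.Wq.shape
        if self.Wk.shape != (d, dm):
            raise DimensionError(f"Wk shape {self.Wk.shape} != Wq shape {(d, dm)}")
        if self.Wv.shape[0] != d:
            raise DimensionError(f"Wv input dim {self.Wv.shape[0]} != {d}")
        if dm % self.n_heads or self.Wv.shape[1] % self.n_heads:
            raise DimensionError("d_m and d must be divisible by n_heads")
        if self.scale == 0.0:
            self.scale = 1.0 / np.sqrt(dm // self.n_heads)

    @property
    def widening_rate(self) -> float:
        return self.Wq.shape[1] / self.Wq.shape[0]


# ---------------------------------------------------------------------------
# window partitioning and cyclic shift
# ---------------------------------------------------------------------------

def _partition_tokens(x, m: int):
    """(B, H, W, d) -> (B, n_windows, M^2, d); works on arrays and Tensors."""
    b, h, w, d = x.shape
    x = x.reshape(b, h // m, m, w // m, m, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, (h // m) * (w // m), m * m, d)


def _merge_tokens(x, m: int, h: int, w: int):
    """Inverse of :func:`_partition_tokens`."""
    b = x.shape[0]
    d = x.shape[-1]
    x = x.reshape(b, h // m, w // m, m, m, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, d)


def partition_windows(grid: FeatureGrid, spec: WindowSpec) -> list:
    """Split a grid into row-major ``M x M`` windows of ``(M^2, d)`` tokens."""
    m = spec.window_side
    if grid.height % m or grid.width % m:
        raise DimensionError(
            f"window_side {m} does not divide grid {grid.height}x{grid.width}"
        )
    x = grid.values.transpose(1, 2, 0)[None]  # (1, H, W, C)
    win = _partition_tokens(x, m)[0]
    return [win[i] for i in range(win.shape[0])]


def merge_windows(windows: list, spec: WindowSpec) -> FeatureGrid:
    """Reassemble row-major windows into the original grid (exact inverse)."""
    m, h, w = spec.window_side, spec.grid_height, spec.grid_width
    if len(windows) != spec.n_windows:
        raise DimensionError(f"expected {spec.n_windows} windows, got {len(windows)}")
    stacked = np.stack(windows)[None]  # (1, nW, M^2, d)
    grid = _merge_tokens(stacked, m, h, w)[0]
    return FeatureGrid(grid.transpose(2, 0, 1))


def cyclic_shift(grid: FeatureGrid, s: int) -> FeatureGrid:
    """Roll features up-left by ``s`` so windows effectively move down-right.

    Negative ``s`` undoes a previous shift.  A pure permutation of pixels.
    """
    bound = min(grid.height, grid.width)
    if not -bound < s < bound:
        raise ValueError(f"shift {s} out of range for grid {grid.height}x{grid.width}")
    return FeatureGrid(np.roll(grid.values, (-s, -s), axis=(1, 2)))


# ---------------------------------------------------------------------------
# shift masks
# ---------------------------------------------------------------------------

def build_shift_masks(spec: WindowSpec) -> MaskSet:
    """Masks blocking attention between tokens from non-adjacent source regions.

    After rolling the grid up-left by ``s``, the last row/column of windows
    mixes tokens wrapped around from the opposite border with tokens that
    stayed put.  Tokens may attend to each other only if both their original
    row blocks and column blocks are contiguous, i.e. they lie on the same
    side of the wrap seam along each axis.
    """
    h, w, m, s = spec.grid_height, spec.grid_width, spec.window_side, spec.shift
    if s == 0:
        zero = np.zeros((m * m, m * m), dtype=np.float32)
        return MaskSet({i: zero.copy() for i in range(spec.n_windows)}, 0)

    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    labels = 2.0 * (rows < s) + 1.0 * (cols < s)  # wrap-seam side labels
    labels = np.roll(labels, (-s, -s), axis=(0, 1))
    win = _partition_tokens(labels[None, :, :, None], m)[0, :, :, 0]  # (nW, M^2)

    masks, patterns = {}, set()
    for i in range(win.shape[0]):
        diff = win[i][:, None] != win[i][None, :]
        mask = np.where(diff, MASK_VALUE, 0.0).astype(np.float32)
        masks[i] = mask
        if diff.any():
            patterns.add(mask.tobytes())
    return MaskSet(masks, len(patterns))


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def _split_heads(x, n_heads: int):
    """(..., T, d) -> (..., heads, T, d/heads)"""
    *lead, t, d = x.shape
    x = x.reshape(*lead, t, n_heads, d // n_heads)
    nd = len(x.shape)
    order = tuple(range(nd - 3)) + (nd - 2, nd - 3, nd - 1)
    return x.transpose(order)


def _merge_heads(x):
    """(..., heads, T, dh) -> (..., T, heads*dh)"""
    nd = len(x.shape)
    order = tuple(range(nd - 3)) + (nd - 2, nd - 3, nd - 1)
    x = x.transpose(order)
    *lead, t, h, dh = x.shape
    return x.reshape(*lead, t, h * dh)


def window_attention(x_i: np.ndarray, params: AttentionParams, mask=None) -> np.ndarray:
    """Widened multi-head self-attention inside one window.

    ``scores = Q K^T * scale + B + mask`` per head, row-softmax, times ``V``;
    head outputs are concatenated back to dimension ``d``.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    if not np.all(np.isfinite(x_i)):
        raise ValueError("non-finite attention input")
    t, d = x_i.shape
    if d != params.Wq.shape[0]:
        raise DimensionError(f"token dim {d} != Wq input dim {params.Wq.shape[0]}")
    h = params.n_heads
    q = _split_heads((x_i @ params.Wq)[None], h)[0]  # (h, T, dm/h)
    k = _split_heads((x_i @ params.Wk)[None], h)[0]
    v = _split_heads((x_i @ params.Wv)[None], h)[0]
    scores = q @ k.transpose(0, 2, 1) * params.scale + params.B
    if mask is not None:
        scores = scores + np.asarray(mask)[None]
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    return _merge_heads((attn @ v)[None])[0]


class WindowedAttention(nn.Module):
    """Tensor (trainable) version of widened window attention, batched over windows."""

    def __init__(self, d: int, spec: WindowSpec, widening_rate: int, n_heads: int,
                 rng: np.random.Generator, shifted: bool, masked: bool = True):
        super().__init__()
        dm = widening_rate * d
        if dm % n_heads or d % n_heads:
            raise DimensionError("d_m and d must be divisible by n_heads")
        self.spec = spec
        self.n_heads = n_heads
        self.shifted = shifted
        self.Wq = nn.Parameter(nn.trunc_normal(rng, (d, dm)))
        self.Wk = nn.Parameter(nn.trunc_normal(rng, (d, dm)))
        self.Wv = nn.Parameter(nn.trunc_normal(rng, (d, d)))
        m2 = spec.window_side ** 2
        self.B = nn.Parameter(np.zeros((n_heads, m2, m2), dtype=np.float32))
        self.scale = 1.0 / np.sqrt(dm // n_heads)
        if shifted and masked and spec.shift > 0:
            mask_set = build_shift_masks(spec)
            stacked = np.stack([mask_set.per_window_mask[i] for i in range(spec.n_windows)])
            self.mask = Tensor(stacked[:, None])  # (nW, 1, M^2, M^2) constant
        else:
            self.mask = None

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, H, W, d) -> (B, H, W, d)"""
        spec = self.spec
        m, s = spec.window_side, spec.shift
        if self.shifted and s > 0:
            x = ad.roll(x, (-s, -s), axes=(1, 2))
        win = _partition_tokens(x, m)  # (B, nW, M^2, d)
        q = _split_heads(ad.matmul(win, self.Wq), self.n_heads)
        k = _split_heads(ad.matmul(win, self.Wk), self.n_heads)
        v = _split_heads(ad.matmul(win, self.Wv), self.n_heads)
        scores = ad.matmul(q, k.transpose(0, 1, 2, 4, 3)) * self.scale + self.B
        if self.mask is not None:
            scores = scores + self.mask
        attn = ad.softmax(scores, axis=-1)
        out = _merge_heads(ad.matmul(attn, v))  # (B, nW, M^2, d)
        out = _merge_tokens(out, m, spec.grid_height, spec.grid_width)
        if self.shifted and s > 0:
            out = ad.roll(out, (s, s), axes=(1, 2))
        return out

    def attention_params(self) -> AttentionParams:
        return AttentionParams(
            Wq=self.Wq.data.copy(), Wk=self.Wk.data.copy(), Wv=self.Wv.data.copy(),
            B=self.B.data.copy(), n_heads=self.n_heads,
        )


class GlobalAttention(nn.Module):
    """Standard multi-head self-attention over all N tokens (consolidation layer)."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d % n_heads:
            raise DimensionError("d must be divisible by n_heads")
        self.n_heads = n_heads
        self.Wq = nn.Parameter(nn.trunc_normal(rng, (d, d)))
        self.Wk = nn.Parameter(nn.trunc_normal(rng, (d, d)))
        self.Wv = nn.Parameter(nn.trunc_normal(rng, (d, d)))
        self.scale = 1.0 / np.sqrt(d // n_heads)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, N, d) -> (B, N, d)"""
        q = _split_heads(ad.matmul(x, self.Wq), self.n_heads)
        k = _split_heads(ad.matmul(x, self.Wk), self.n_heads)
        v = _split_heads(ad.matmul(x, self.Wv), self.n_heads)
        scores = ad.matmul(q, k.transpose(0, 1, 3, 2)) * self.scale
        attn = ad.softmax(scores, axis=-1)
        return _merge_heads(ad.matmul(attn, v))


class SlidingWindowTransformerBlock(nn.Module):
    """The full SWTB:

    ``z0' = W-MSA(LN(z0)) + z0``
    ``z1  = FFN(LN(z0')) + z0'``
    ``z1' = SW-MSA(LN(z1)) + z1``   (cyclically shifted and masked)
    ``z2  = FFN(LN(z1')) + z1'``
    followed by one global self-attention layer with residual.

    With ``use_sliding_window=False`` the second attention runs unshifted and
    unmasked (the ablation arm).
    """

    def __init__(self, d: int, grid_height: int, grid_width: int, window_side: int = 4,
                 shift: int = 2, widening_rate: int = 2, n_heads: int = 4,
                 use_sliding_window: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d = d
        self.grid_height, self.grid_width = grid_height, grid_width
        base = WindowSpec(window_side, 0, grid_height, grid_width)
        sw_shift = shift if use_sliding_window else 0
        self.spec = WindowSpec(window_side, sw_shift, grid_height, grid_width)
        self.ln1 = nn.LayerNorm(d)
        self.wmsa = WindowedAttention(d, base, widening_rate, n_heads, rng, shifted=False)
        self.ln2 = nn.LayerNorm(d)
        self.ffn1 = nn.FeedForward(d, rng)
        self.ln3 = nn.LayerNorm(d)
        self.swmsa = WindowedAttention(d, self.spec, widening_rate, n_heads, rng,
                                       shifted=use_sliding_window,
                                       masked=use_sliding_window)
        self.ln4 = nn.LayerNorm(d)
        self.ffn2 = nn.FeedForward(d, rng)
        self.ln5 = nn.LayerNorm(d)
        self.global_attn = GlobalAttention(d, n_heads, rng)

    # each step is LN -> sublayer -> residual, on (B, N, d)
    def _as_grid(self, z: Tensor) -> Tensor:
        b, n, d = z.shape
        return z.reshape(b, self.grid_height, self.grid_width, d)

    def _as_seq(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        return x.reshape(b, self.grid_height * self.grid_width, self.d)

    def step_wmsa(self, z0: Tensor) -> Tensor:
        return self._as_seq(self.wmsa(self._as_grid(self.ln1(z0)))) + z0

    def step_ffn1(self, z0p: Tensor) -> Tensor:
        return self.ffn1(self.ln2(z0p)) + z0p

    def step_swmsa(self, z1: Tensor) -> Tensor:
        return self._as_seq(self.swmsa(self._as_grid(self.ln3(z1)))) + z1

    def step_ffn2(self, z1p: Tensor) -> Tensor:
        return self.ffn2(self.ln4(z1p)) + z1p

    def step_global(self, z2: Tensor) -> Tensor:
        return self.global_attn(self.ln5(z2)) + z2

    def forward(self, z: Tensor) -> Tensor:
        """z: (B, N, d) -> (B, N, d)"""
        if z.shape[1] != self.grid_height * self.grid_width or z.shape[2] != self.d:
            raise DimensionError(
                f"sequence shape {z.shape[1:]} incompatible with "
                f"{self.grid_height}x{self.grid_width} grid of dim {self.d}"
            )
        z = self.step_wmsa(z)
        z = self.step_ffn1(z)
        z = self.step_swmsa(z)
        z = self.step_ffn2(z)
        return self.step_global(z)


def swtb_forward(z0: TokenSequence, block: SlidingWindowTransformerBlock) -> TokenSequence:
    """Run the SWTB on a ``(d, N)`` token sequence (non-batched, inference)."""
    if z0.grid_height != block.grid_height or z0.grid_width != block.grid_width:
        raise DimensionError(
            f"sequence grid {z0.grid_height}x{z0.grid_width} != block grid "
            f"{block.grid_height}x{block.grid_width}"
        )
    if z0.token_dim != block.d:
        raise DimensionError(f"token dim {z0.token_dim} != block dim {block.d}")
    with ad.no_grad():
        z = Tensor(z0.values.T[None])  # (1, N, d)
        out = block(z).data[0].T
    return TokenSequence(out, z0.grid_height, z0.grid_width, stage_tag="z2")


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

def attention_cost(H: int, W: int, C: int, M: int) -> tuple:
    """Operation counts of global vs windowed attention on an ``H x W x C`` map.

    ``cost_w_msa  = 4 H W C^2 + 2 H^2 W^2 C``  (all-pairs attention)
    ``cost_sw_msa = 4 H W C^2 + 2 M^2 H W C``  (attention within M x M windows)
    """
    for name, v in (("H", H), ("W", W), ("C", C), ("M", M)):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    H, W, C, M = int(H), int(W), int(C), int(M)
    cost_w = 4 * H * W * C**2 + 2 * H**2 * W**2 * C
    cost_sw = 4 * H * W * C**2 + 2 * M**2 * H * W * C
    return cost_w, cost_sw
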