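"""Window partitioning, cyclic shift, shift masks, widened attention, SWTB."""

import numpy as np
import pytest

from swunet import autodiff as ad
from swunet.autodiff import Tensor
from swunet.model_core import (
    MASK_VALUE,
    AttentionParams,
    DimensionError,
    FeatureGrid,
    SlidingWindowTransformerBlock,
    TokenSequence,
    WindowSpec,
    attention_cost,
    build_shift_masks,
    cyclic_shift,
    merge_windows,
    partition_windows,
    swtb_forward,
    window_attention,
)


def random_grid(rng, c, h, w):
    return FeatureGrid(rng.standard_normal((c, h, w)))


def make_params(rng, d=8, n_heads=2, widen=2, m=4, zero_bias=True):
    dm = widen * d
    b = np.zeros((n_heads, m * m, m * m)) if zero_bias else rng.standard_normal(
        (n_heads, m * m, m * m)
    ) * 0.1
    return AttentionParams(
        Wq=rng.standard_normal((d, dm)) * 0.2,
        Wk=rng.standard_normal((d, dm)) * 0.2,
        Wv=rng.standard_normal((d, d)) * 0.2,
        B=b,
        n_heads=n_heads,
    )


# ---------------------------------------------------------------------------
# partitioning and shifting
# ---------------------------------------------------------------------------

class TestWindows:
    @pytest.mark.parametrize("h,w,m,n_expected", [(32, 32, 4, 64), (4, 4, 4, 1), (8, 16, 4, 8)])
    def test_window_count_and_token_size(self, rng, h, w, m, n_expected):
        grid = random_grid(rng, 3, h, w)
        spec = WindowSpec(m, 0, h, w)
        wins = partition_windows(grid, spec)
        assert len(wins) == n_expected
        assert all(win.shape == (m * m, 3) for win in wins)

    @pytest.mark.parametrize("h,w", [(8, 8), (32, 16)])
    def test_partition_merge_round_trip_is_exact(self, rng, h, w):
        grid = random_grid(rng, 5, h, w)
        spec = WindowSpec(4, 0, h, w)
        back = merge_windows(partition_windows(grid, spec), spec)
        assert np.array_equal(back.values, grid.values)

    def test_non_divisible_dims_raise_naming_both_values(self, rng):
        grid = random_grid(rng, 1, 6, 8)
        with pytest.raises(DimensionError, match="4.*6x8"):
            partition_windows(grid, WindowSpec(4, 0, 8, 8))

    def test_first_window_is_topleft_block(self, rng):
        grid = random_grid(rng, 2, 8, 8)
        wins = partition_windows(grid, WindowSpec(4, 0, 8, 8))
        expected = grid.values[:, :4, :4].transpose(1, 2, 0).reshape(16, 2)
        assert np.array_equal(wins[0], expected)


class TestCyclicShift:
    def test_zero_shift_is_identity(self, rng):
        grid = random_grid(rng, 2, 8, 8)
        assert np.array_equal(cyclic_shift(grid, 0).values, grid.values)

    def test_shift_then_unshift_is_identity(self, rng):
        grid = random_grid(rng, 3, 16, 16)
        back = cyclic_shift(cyclic_shift(grid, 3), -3)
        assert np.array_equal(back.values, grid.values)

    def test_shift_preserves_value_multiset(self, rng):
        grid = random_grid(rng, 1, 4, 4)
        shifted = cyclic_shift(grid, 2)
        assert np.array_equal(np.sort(shifted.values.ravel()), np.sort(grid.values.ravel()))

    def test_out_of_range_shift_raises(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            cyclic_shift(random_grid(rng, 1, 4, 4), 4)

    def test_windows_move_down_right(self, rng):
        # the value at (0, 0) must end up at (H-s, W-s) after the roll
        grid = random_grid(rng, 1, 8, 8)
        shifted = cyclic_shift(grid, 2)
        assert shifted.values[0, 6, 6] == grid.values[0, 0, 0]


# ---------------------------------------------------------------------------
# shift masks
# ---------------------------------------------------------------------------

def oracle_allowed(spec):
    """Brute-force adjacency oracle on original token coordinates.

    Two tokens in a shifted window may interact iff they lie on the same side
    of the wrap seam along BOTH axes (rows < s wrapped from the top edge,
    likewise columns).  Returns {window_index: (M^2, M^2) bool array}.
    """
    h, w, m, s = spec.grid_height, spec.grid_width, spec.window_side, spec.shift
    out = {}
    for wi in range(spec.n_windows):
        wr, wc = divmod(wi, w // m)
        allowed = np.zeros((m * m, m * m), dtype=bool)
        for a in range(m * m):
            for b in range(m * m):
                ra, ca = wr * m + a // m, wc * m + a % m
                rb, cb = wr * m + b // m, wc * m + b % m
                # original (pre-shift) coordinates
                ora, oca = (ra + s) % h, (ca + s) % w
                orb, ocb = (rb + s) % h, (cb + s) % w
                same_row_side = (ora < s) == (orb < s)
                same_col_side = (oca < s) == (ocb < s)
                allowed[a, b] = same_row_side and same_col_side
        out[wi] = allowed
    return out


class TestShiftMasks:
    def test_reference_grid_has_three_distinct_patterns(self):
        masks = build_shift_masks(WindowSpec(4, 2, 32, 32))
        assert masks.n_distinct_patterns == 3

    def test_zero_shift_yields_no_patterns_and_all_zero_masks(self):
        masks = build_shift_masks(WindowSpec(4, 0, 32, 32))
        assert masks.n_distinct_patterns == 0
        assert all(np.all(m == 0) for m in masks.per_window_mask.values())

    @pytest.mark.parametrize("h,w", [(8, 8), (8, 12), (16, 16)])
    def test_masks_match_bruteforce_adjacency_oracle(self, h, w):
        spec = WindowSpec(4, 2, h, w)
        masks = build_shift_masks(spec)
        allowed = oracle_allowed(spec)
        for wi in range(spec.n_windows):
            expected = np.where(allowed[wi], 0.0, MASK_VALUE)
            assert np.array_equal(masks.per_window_mask[wi], expected), f"window {wi}"

    def test_masks_are_symmetric(self):
        masks = build_shift_masks(WindowSpec(4, 2, 8, 8))
        for m in masks.per_window_mask.values():
            assert np.array_equal(m, m.T)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def dense_attention_oracle(x, wq, wk, wv, n_heads, scale):
    """Explicit per-head double-loop softmax attention."""
    t, d = x.shape
    dm = wq.shape[1]
    dh_qk, dh_v = dm // n_heads, d // n_heads
    q, k, v = x @ wq, x @ wk, x @ wv
    out = np.zeros((t, d))
    for h in range(n_heads):
        qs = q[:, h * dh_qk : (h + 1) * dh_qk]
        ks = k[:, h * dh_qk : (h + 1) * dh_qk]
        vs = v[:, h * dh_v : (h + 1) * dh_v]
        for i in range(t):
            scores = np.array([qs[i] @ ks[j] * scale for j in range(t)])
            e = np.exp(scores - scores.max())
            attn = e / e.sum()
            out[i, h * dh_v : (h + 1) * dh_v] = sum(attn[j] * vs[j] for j in range(t))
    return out


class TestWindowAttention:
    def test_zero_value_projection_gives_zero_output(self, rng):
        params = make_params(rng)
        params.Wv[:] = 0.0
        x = rng.standard_normal((16, 8))
        assert np.allclose(window_attention(x, params), 0.0)

    def test_matches_dense_double_loop_oracle(self, rng):
        params = make_params(rng)
        x = rng.standard_normal((16, 8))
        out = window_attention(x, params)
        ref = dense_attention_oracle(x, params.Wq, params.Wk, params.Wv,
                                     params.n_heads, params.scale)
        assert np.allclose(out, ref, atol=1e-5)

    def test_masked_pairs_receive_negligible_weight(self, rng):
        # recompute the post-softmax weights and check masked entries vanish
        params = make_params(rng, zero_bias=False)
        mask = np.zeros((16, 16))
        mask[:8, 8:] = MASK_VALUE
        mask[8:, :8] = MASK_VALUE
        x = rng.standard_normal((16, 8))
        q = (x @ params.Wq).reshape(16, 2, 8).transpose(1, 0, 2)
        k = (x @ params.Wk).reshape(16, 2, 8).transpose(1, 0, 2)
        scores = q @ k.transpose(0, 2, 1) * params.scale + params.B + mask[None]
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn = e / e.sum(axis=-1, keepdims=True)
        assert attn[:, :8, 8:].max() < 1e-6
        assert attn[:, 8:, :8].max() < 1e-6
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_non_finite_input_raises(self, rng):
        params = make_params(rng)
        x = np.full((16, 8), np.nan)
        with pytest.raises(ValueError, match="finite"):
            window_attention(x, params)

    def test_dimension_mismatch_raises(self, rng):
        params = make_params(rng, d=8)
        with pytest.raises(DimensionError):
            window_attention(rng.standard_normal((16, 6)), params)


# ---------------------------------------------------------------------------
# the full block
# ---------------------------------------------------------------------------

class TestSWTB:
    def make_block(self, use_sw=True, d=8, side=8):
        return SlidingWindowTransformerBlock(
            d, side, side, window_side=4, shift=2, widening_rate=2, n_heads=2,
            use_sliding_window=use_sw, rng=np.random.default_rng(3),
        )

    def test_zero_weights_make_block_an_identity(self):
        block = self.make_block()
        # zero all weight matrices and biases, keep LN gains (output of each
        # sublayer is then zero and only the residuals survive)
        for name, p in block.named_parameters():
            if not name.endswith("gain"):
                p.data[:] = 0.0
        z = Tensor(np.random.default_rng(0).standard_normal((1, 64, 8)).astype(np.float32))
        out = block(z)
        assert np.allclose(out.data, z.data, atol=1e-6)

    def test_output_shape_matches_input_shape(self):
        block = self.make_block()
        z = Tensor(np.random.default_rng(1).standard_normal((2, 64, 8)).astype(np.float32))
        assert block(z).shape == (2, 64, 8)

    def test_forward_equals_staged_composition(self):
        block = self.make_block()
        z = Tensor(np.random.default_rng(2).standard_normal((1, 64, 8)).astype(np.float32))
        staged = block.step_global(
            block.step_ffn2(block.step_swmsa(block.step_ffn1(block.step_wmsa(z))))
        )
        assert np.array_equal(block(z).data, staged.data)

    def test_sequence_api_round_trip(self):
        block = self.make_block()
        z0 = TokenSequence(np.random.default_rng(4).standard_normal((8, 64)), 8, 8, "z0")
        z2 = swtb_forward(z0, block)
        assert z2.values.shape == (8, 64)
        assert z2.stage_tag == "z2"

    def test_sequence_grid_mismatch_raises(self):
        block = self.make_block()
        z0 = TokenSequence(np.random.default_rng(4).standard_normal((8, 16)), 4, 4)
        with pytest.raises(DimensionError):
            swtb_forward(z0, block)

    def test_no_leakage_across_mask_entries(self):
        """Perturbing one token changes only tokens allowed to see it.

        With all weights except the shifted attention zeroed, the block output
        is z + SW-MSA(LN(z)); perturbing token t may change output tokens u
        only when some window has both u unmasked from t.
        """
        side, d = 8, 8
        block = self.make_block(d=d, side=side)
        spec = block.spec
        rng = np.random.default_rng(5)
        z = rng.standard_normal((1, side * side, d)).astype(np.float32)

        def swmsa_out(arr):
            with ad.no_grad():
                return block.step_swmsa(Tensor(arr)).data[0]

        base = swmsa_out(z)
        allowed = oracle_allowed(spec)
        s, m = spec.shift, spec.window_side
        # map each token to (window, slot) after the cyclic shift
        token_window = {}
        for r in range(side):
            for c in range(side):
                rs, cs = (r - s) % side, (c - s) % side
                wi = (rs // m) * (side // m) + cs // m
                slot = (rs % m) * m + cs % m
                token_window[r * side + c] = (wi, slot)

        for t in [0, 13, 37, 63]:
            zp = z.copy()
            zp[0, t] += 5.0
            delta = np.abs(swmsa_out(zp) - base).max(axis=1)
            wi_t, slot_t = token_window[t]
            for u in range(side * side):
                wi_u, slot_u = token_window[u]
                reachable = (u == t) or (wi_u == wi_t and allowed[wi_u][slot_u, slot_t])
                if not reachable:
                    assert delta[u] < 1e-5, f"leak from token {t} to {u}"


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

class TestAttentionCost:
    def test_reference_operating_point(self):
        cost_w, cost_sw = attention_cost(32, 32, 256, 4)
        assert cost_w == 805_306_368  # prints as "800 million"
        assert cost_sw == 276_824_064  # prints as "270 million"

    def test_costs_equal_when_window_covers_grid(self):
        cost_w, cost_sw = attention_cost(8, 8, 16, 8)
        assert cost_w == cost_sw

    def test_windowed_never_exceeds_global_and_grows_with_channels(self):
        for c in (8, 16, 32):
            cost_w, cost_sw = attention_cost(16, 16, c, 4)
            assert cost_sw <= cost_w
        costs = [attention_cost(16, 16, c, 4) for c in (8, 16, 32)]
        assert costs[0][0] < costs[1][0] < costs[2][0]
        assert costs[0][1] < costs[1][1] < costs[2][1]

    def test_non_positive_input_raises(self):
        with pytest.raises(ValueError):
            attention_cost(0, 32, 256, 4)
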