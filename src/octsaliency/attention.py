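"""Transformer attention attribution for shifted-window backbones.

Attention probabilities are gradient-weighted (rectified product with the
gradient of the target-class logit), reduced to per-token importances via
incoming-attention mass, mapped back to the block's spatial grid by window
reversal (undoing any cyclic shift), upsampled, normalised, and fused across
early/late depths with 0.4/0.6 weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .backbone import WindowedAttentionCapture
from .postprocess import Heatmap, minmax_norm, upsample_bilinear

__all__ = [
    "FusionWeights",
    "window_partition",
    "window_reverse",
    "relevance_to_importance",
    "el_gwaa",
    "self_attention_map",
]


@dataclass(frozen=True)
class FusionWeights:
    """Early/late mixing weights; late evidence carries the larger weight."""

    w_early: float = 0.4
    w_late: float = 0.6

    def __post_init__(self):
        if self.w_early < 0 or self.w_late < 0:
            raise ValueError("fusion weights must be nonnegative")
        if abs(self.w_early + self.w_late - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")


def window_partition(grid: np.ndarray, w: int, s: int = 0) -> np.ndarray:
    """Tile an H x W grid into w x w windows after a cyclic roll by -s.

    Returns ((H/w)*(W/w), w, w) in row-major window order.
    """
    grid = np.asarray(grid)
    H, W = grid.shape
    if H % w or W % w:
        raise ValueError(f"window size {w} must divide grid {H}x{W}")
    if not 0 <= s < w:
        raise ValueError("shift must satisfy 0 <= s < w")
    rolled = np.roll(grid, (-s, -s), axis=(0, 1))
    return (
        rolled.reshape(H // w, w, W // w, w)
        .transpose(0, 2, 1, 3)
        .reshape(-1, w, w)
    )


def window_reverse(windows: np.ndarray, H: int, W: int, w: int, s: int = 0) -> np.ndarray:
    """Exact inverse of :func:`window_partition`, including undoing the shift."""
    windows = np.asarray(windows)
    if windows.shape != ((H // w) * (W // w), w, w):
        raise ValueError("window count inconsistent with grid and window size")
    grid = (
        windows.reshape(H // w, W // w, w, w)
        .transpose(0, 2, 1, 3)
        .reshape(H, W)
    )
    return np.roll(grid, (s, s), axis=(0, 1))


def relevance_to_importance(att: WindowedAttentionCapture) -> np.ndarray:
    """Incoming-attention mass of rectified gradient-weighted attention.

    R = ReLU(probs * grad) per head; token j's importance is the column sum
    over queries i, averaged over heads.  Returns (num_windows, w, w).
    """
    if att.grad is None:
        raise ValueError("attention capture has no gradients")
    if att.grad.shape != att.probs.shape:
        raise ValueError("gradient and probability shapes differ")
    R = np.maximum(att.probs * att.grad, 0.0)  # (nW, heads, N, N)
    imp = R.sum(axis=2).mean(axis=1)  # column sums over queries, head mean
    w = att.window_size
    return imp.reshape(-1, w, w)


def _block_map(att: WindowedAttentionCapture, side: int) -> np.ndarray:
    """One block's importances reversed to its grid, upsampled, normalised."""
    H, W = att.grid
    grid = window_reverse(relevance_to_importance(att), H, W, att.window_size, att.shift_size)
    return minmax_norm(upsample_bilinear(grid, side))


def el_gwaa(
    early: Sequence[WindowedAttentionCapture],
    late: Sequence[WindowedAttentionCapture],
    fw: FusionWeights = FusionWeights(),
    input_side: int = 256,
    target_class: int | str = "agnostic",
) -> Heatmap:
    """Early-late gradient-weighted window attention aggregation.

    Per-block maps are averaged within the early and the late group, then
    combined as ``minmax(w_early * E + w_late * L)``.
    """
    if not early or not late:
        raise ValueError("both early and late block lists must be non-empty")
    E = np.mean([_block_map(a, input_side) for a in early], axis=0)
    L = np.mean([_block_map(a, input_side) for a in late], axis=0)
    fused = minmax_norm(fw.w_early * E + fw.w_late * L)
    return Heatmap(fused, method_id="elgwaa", target_class=target_class)


def self_attention_map(
    last: WindowedAttentionCapture,
    input_side: int = 256,
    target_class: int | str = "agnostic",
) -> Heatmap:
    """Gradient-weighted relevance of the final attention block only."""
    return Heatmap(_block_map(last, input_side), method_id="selfattn",
                   target_class=target_class)
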