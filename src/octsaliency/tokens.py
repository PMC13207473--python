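"""TRAST: token-contrast saliency from normalisation-output descriptors.

Each token is compared to the image's global (mean-pooled) token descriptor
by cosine similarity; the similarity is inverted so that locally distinctive
tokens score high, min-max normalised, and reshaped to the block's spatial
grid.  The method is gradient-free and class-agnostic.  Variant vs1 fuses
early and late depths with a larger late weight; vs2 keeps them as separate
layers rendered base + translucent top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .attention import FusionWeights
from .backbone import BlockAddress, TokenCapture
from .postprocess import Heatmap, LayeredHeatmap, minmax_norm, upsample_bilinear

__all__ = [
    "TokenBlockDescriptor",
    "token_contrast_map",
    "trast_v1",
    "trast_v2",
]


@dataclass
class TokenBlockDescriptor:
    """N x C token matrix from one block's normalisation output."""

    tokens: np.ndarray
    grid: tuple[int, int]
    address: BlockAddress | None = None
    source: str = "norm2"

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 2:
            raise ValueError("need an N x C token matrix with N >= 2")
        if not np.all(np.isfinite(self.tokens)):
            raise ValueError("non-finite token descriptors")
        if self.grid[0] * self.grid[1] != self.tokens.shape[0]:
            raise ValueError("grid does not match token count")

    @staticmethod
    def from_capture(cap: TokenCapture) -> "TokenBlockDescriptor":
        return TokenBlockDescriptor(cap.tokens, cap.grid, cap.address, cap.source)


def token_contrast_map(d: TokenBlockDescriptor) -> np.ndarray:
    """Inverted, normalised cosine similarity of each token to the global mean.

    g = mean over tokens; s_i = cos(t_i, g) (0 where either norm < 1e-12);
    raw_i = 1 - s_i; min-max normalise; reshape to the grid.
    """
    t = d.tokens
    g = t.mean(axis=0)
    tn = np.linalg.norm(t, axis=1)
    gn = np.linalg.norm(g)
    denom = tn * gn
    s = np.where(denom > 1e-12, (t @ g) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    return minmax_norm(1.0 - s).reshape(d.grid)


def _group_map(descs: Sequence[TokenBlockDescriptor], side: int) -> np.ndarray:
    """Mean of per-block contrast maps, each upsampled to the input side."""
    return np.mean([upsample_bilinear(token_contrast_map(d), side) for d in descs], axis=0)


def trast_v1(
    early: Sequence[TokenBlockDescriptor],
    late: Sequence[TokenBlockDescriptor],
    fw: FusionWeights = FusionWeights(),
    input_side: int = 256,
) -> Heatmap:
    """Fused variant: minmax(w_early * E + w_late * L), late emphasised."""
    if not early or not late:
        raise ValueError("both early and late descriptor lists must be non-empty")
    if fw.w_late <= fw.w_early:
        raise ValueError("vs1 requires the late weight to exceed the early weight")
    E = _group_map(early, input_side)
    L = _group_map(late, input_side)
    return Heatmap(minmax_norm(fw.w_early * E + fw.w_late * L), method_id="trast_vs1")


def trast_v2(
    early: Sequence[TokenBlockDescriptor],
    late: Sequence[TokenBlockDescriptor],
    input_side: int = 256,
) -> LayeredHeatmap:
    """Layered variant: independently normalised early (base) and late (top)
    maps; late evidence dominates where strong, early remains visible where
    it is weak."""
    if not early or not late:
        raise ValueError("both early and late descriptor lists must be non-empty")
    base = minmax_norm(_group_map(early, input_side))
    top = minmax_norm(_group_map(late, input_side))
    return LayeredHeatmap(base=base, top=top, method_id="trast_vs2")
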