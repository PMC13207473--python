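"""Shared heatmap plumbing: normalisation, upsampling, overlays and panels.

Every saliency method ends in the same contract — a unit-interval map,
min-max normalised within the image and bilinearly upsampled to the input
resolution — so those operations live here, together with overlay rendering
and the randomized questionnaire-panel assembly used for blinded review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .preprocess import StandardImage

__all__ = [
    "Heatmap",
    "LayeredHeatmap",
    "PanelSpec",
    "minmax_norm",
    "upsample_bilinear",
    "overlay",
    "composite_layered",
    "build_panel",
]


@dataclass
class Heatmap:
    """Input-resolution relevance map in [0,1], tagged with its method."""

    values: np.ndarray
    method_id: str = ""
    target_class: int | str = "agnostic"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("heatmap contains non-finite values")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("heatmap values must lie in [0,1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class LayeredHeatmap:
    """Two independently normalised maps rendered as base + translucent top.

    The rendered intensity is ``max(top, base * (1 - top))``: the top layer
    dominates where it is strong, the base remains visible where it is weak.
    """

    base: np.ndarray
    top: np.ndarray
    compositing: str = "top-opacity"
    method_id: str = ""
    target_class: int | str = "agnostic"

    def __post_init__(self):
        self.base = np.clip(np.asarray(self.base, dtype=np.float64), 0, 1)
        self.top = np.clip(np.asarray(self.top, dtype=np.float64), 0, 1)
        if self.base.shape != self.top.shape:
            raise ValueError("base and top maps must share a shape")


@dataclass
class PanelSpec:
    image_id: str = ""
    methods: tuple[str, ...] = ()
    order_seed: int = 42
    alpha: float = 0.4
    colormap: str = "jet"


def minmax_norm(m: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """(m - min) / (max - min); degenerate (constant) maps become all zeros."""
    m = np.asarray(m, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite entries in map")
    lo, hi = m.min(), m.max()
    if hi - lo < tol:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def upsample_bilinear(m: np.ndarray, side: int = 256) -> np.ndarray:
    """Bilinear resize to side x side (align-corners-off pixel-centre
    convention; constant maps stay exactly constant)."""
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("expected a 2D map")
    if m.shape == (side, side):
        return m.copy()
    return _sk_resize(m, (side, side), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def composite_layered(lh: LayeredHeatmap) -> np.ndarray:
    """Flatten a layered map to a single intensity map for display."""
    return np.maximum(lh.top, lh.base * (1.0 - lh.top))


def _colorize(values: np.ndarray, cmap_name: str) -> np.ndarray:
    cmap = colormaps[cmap_name]
    return np.asarray(cmap(np.clip(values, 0, 1))[..., :3], dtype=np.float64)


def overlay(
    std: StandardImage,
    h: Heatmap | LayeredHeatmap,
    alpha: float = 0.4,
    colormap: str = "jet",
    zero_transparent: bool = True,
) -> np.ndarray:
    """Alpha-blend a colormapped heatmap over the grayscale B-scan.

    Returns a uint8 RGB array.  With `zero_transparent`, pixels where the
    map is exactly zero show the unmodified image.
    """
    vals = composite_layered(h) if isinstance(h, LayeredHeatmap) else h.values
    if vals.shape != std.gray.shape:
        raise ValueError("heatmap and image shapes differ")
    base = np.repeat(std.gray[:, :, None], 3, axis=2)
    color = _colorize(vals, colormap)
    a = np.full(vals.shape, alpha)
    if zero_transparent:
        a = np.where(vals == 0.0, 0.0, a)
    out = base * (1 - a[:, :, None]) + color * a[:, :, None]
    return np.round(np.clip(out, 0, 1) * 255).astype(np.uint8)


@dataclass
class Panel:
    image: np.ndarray  # uint8 RGB, original + one slot per method
    order_key: dict[int, str] = field(default_factory=dict)  # slot -> method id


def build_panel(
    std: StandardImage,
    maps: dict[str, Heatmap | LayeredHeatmap],
    spec: PanelSpec,
) -> Panel:
    """Assemble the original image plus per-method overlays in a reproducibly
    randomized order, emitting the slot->method key for later unblinding."""
    if not maps:
        raise ValueError("at least one heatmap required")
    methods = list(spec.methods) if spec.methods else sorted(maps)
    rng = np.random.default_rng(spec.order_seed)
    order = [methods[i] for i in rng.permutation(len(methods))]
    tiles = [np.round(np.repeat(std.gray[:, :, None], 3, axis=2) * 255).astype(np.uint8)]
    key: dict[int, str] = {}
    for slot, mid in enumerate(order):
        tiles.append(overlay(std, maps[mid], alpha=spec.alpha, colormap=spec.colormap))
        key[slot] = mid
    gap = np.full((std.gray.shape[0], 4, 3), 255, dtype=np.uint8)
    row: list[np.ndarray] = []
    for i, tile in enumerate(tiles):
        if i:
            row.append(gap)
        row.append(tile)
    return Panel(image=np.concatenate(row, axis=1), order_key=key)
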