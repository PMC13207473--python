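"""CGFM: fusion of a class-conditional Grad-CAM branch with a class-agnostic
token-similarity branch.

vs1 keeps the two maps as separate layers (token similarity as base,
Grad-CAM as top); vs2 multiplies them elementwise, prioritising
intersectional evidence; the weighted variant interpolates linearly with a
continuous coefficient alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import CaptureSpec, ClassifierModel, forward_with_capture
from .cam import gradient_cam
from .postprocess import Heatmap, LayeredHeatmap, minmax_norm, upsample_bilinear
from .tokens import TokenBlockDescriptor, token_contrast_map

__all__ = ["CgfmConfig", "cgfm", "cgfm_branches"]


@dataclass
class CgfmConfig:
    variant: str = "weighted"  # "vs1", "vs2" or "weighted"
    alpha: float = 0.5  # weighted only: weight of the token-similarity branch

    def __post_init__(self):
        if self.variant not in ("vs1", "vs2", "weighted"):
            raise ValueError(f"unknown CGFM variant {self.variant!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0,1]")


def cgfm(tfs: np.ndarray, cam: np.ndarray, cfg: CgfmConfig,
         target_class: int | str = "agnostic"):
    """Fuse unit-interval token-similarity and Grad-CAM maps."""
    tfs = np.asarray(tfs, dtype=np.float64)
    cam = np.asarray(cam, dtype=np.float64)
    if tfs.shape != cam.shape:
        raise ValueError("branch maps must share a shape")
    for name, m in (("tfs", tfs), ("cam", cam)):
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError(f"{name} map must be min-max normalised to [0,1]")
    if cfg.variant == "vs1":
        return LayeredHeatmap(base=tfs, top=cam, method_id="cgfm_vs1",
                              target_class=target_class)
    if cfg.variant == "vs2":
        return Heatmap(minmax_norm(tfs * cam), method_id="cgfm_vs2",
                       target_class=target_class)
    fused = cfg.alpha * tfs + (1.0 - cfg.alpha) * cam
    return Heatmap(minmax_norm(fused), method_id="cgfm_weighted",
                   target_class=target_class)


def cgfm_branches(
    model: ClassifierModel,
    x: np.ndarray,
    target_class: int | str = "predicted",
    late_blocks: int = 2,
    input_side: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Compute the two constituent maps at input resolution.

    The token-similarity branch is the mean of the last `late_blocks` blocks'
    contrast maps (as in TRAST's late map); the CAM branch is Grad-CAM at the
    resolved target layer for the same target class.  Returns
    (tfs map, cam map, resolved target class), each min-max normalised.
    """
    side = input_side or model.spec.input_side
    total = model.spec.total_blocks
    late = tuple(range(total - late_blocks, total))
    spec = CaptureSpec(norm_tokens_at=late, final_norm=True,
                       target_activation=True, want_gradients=True)
    bundle = forward_with_capture(model, x, spec, target_class=target_class)
    descs = [TokenBlockDescriptor.from_capture(bundle.tokens[g]) for g in late]
    tfs = minmax_norm(np.mean(
        [upsample_bilinear(token_contrast_map(d), side) for d in descs], axis=0
    ))
    raw = gradient_cam("gradcam", bundle.activation.activation,
                       bundle.activation.grad, bundle.target_class)
    cam = minmax_norm(upsample_bilinear(raw.values, side))
    return tfs, cam, bundle.target_class
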