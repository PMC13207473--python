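"""End-to-end registry of the twelve heatmap variants.

Each entry maps a method identifier to a callable
``(model, x, target_class="predicted", **kw) -> Heatmap | LayeredHeatmap``
producing an input-resolution unit-interval map for the model-predicted
class (where the method is class-conditional).  Early blocks are the first
two global block indices, late blocks the last two.
"""

from __future__ import annotations

import numpy as np

from .attention import FusionWeights, el_gwaa, self_attention_map
from .backbone import CaptureSpec, ClassifierModel, forward_with_capture
from .cam import eigen_cam, gradient_cam, score_cam
from .hybrid import CgfmConfig, cgfm, cgfm_branches
from .postprocess import Heatmap, LayeredHeatmap, minmax_norm, upsample_bilinear
from .tokens import TokenBlockDescriptor, trast_v1, trast_v2

__all__ = ["METHOD_IDS", "compute_heatmap", "compute_all"]

METHOD_IDS = (
    "gradcam",
    "gradcampp",
    "scorecam",
    "eigencam",
    "hirescam",
    "elgwaa",
    "selfattn",
    "trast_vs1",
    "trast_vs2",
    "cgfm_vs1",
    "cgfm_vs2",
    "cgfm_weighted",
)


def _early_late(model: ClassifierModel) -> tuple[tuple[int, int], tuple[int, int]]:
    total = model.spec.total_blocks
    return (0, 1), (total - 2, total - 1)


def _cam_capture(model, x, target_class, want_gradients=True):
    spec = CaptureSpec(final_norm=True, target_activation=True,
                       want_gradients=want_gradients)
    return forward_with_capture(model, x, spec, target_class=target_class)


def _finish(raw: np.ndarray, side: int, method_id: str, target) -> Heatmap:
    return Heatmap(minmax_norm(upsample_bilinear(raw, side)),
                   method_id=method_id, target_class=target)


def compute_heatmap(
    model: ClassifierModel,
    x: np.ndarray,
    method: str,
    target_class: int | str = "predicted",
    fusion: FusionWeights = FusionWeights(),
    scorecam_k: int = 64,
    cgfm_alpha: float = 0.5,
):
    """Compute one method's heatmap at the model's input resolution."""
    side = model.spec.input_side
    early, late = _early_late(model)

    if method in ("gradcam", "gradcampp", "hirescam"):
        b = _cam_capture(model, x, target_class)
        raw = gradient_cam(method, b.activation.activation, b.activation.grad,
                           b.target_class)
        return _finish(raw.values, side, method, b.target_class)

    if method == "scorecam":
        raw = score_cam(model, x, target_class=target_class, k=scorecam_k)
        return _finish(raw.values, side, method, raw.target_class)

    if method == "eigencam":
        b = _cam_capture(model, x, target_class, want_gradients=False)
        raw = eigen_cam(b.activation.activation)
        return _finish(raw.values, side, method, "agnostic")

    if method in ("elgwaa", "selfattn"):
        blocks = early + late if method == "elgwaa" else (late[-1],)
        spec = CaptureSpec(attention_at=blocks, want_gradients=True)
        b = forward_with_capture(model, x, spec, target_class=target_class)
        if method == "selfattn":
            return self_attention_map(b.attention[late[-1]], input_side=side,
                                      target_class=b.target_class)
        return el_gwaa([b.attention[g] for g in early],
                       [b.attention[g] for g in late],
                       fw=fusion, input_side=side, target_class=b.target_class)

    if method in ("trast_vs1", "trast_vs2"):
        spec = CaptureSpec(norm_tokens_at=early + late, want_gradients=False)
        b = forward_with_capture(model, x, spec)
        ed = [TokenBlockDescriptor.from_capture(b.tokens[g]) for g in early]
        ld = [TokenBlockDescriptor.from_capture(b.tokens[g]) for g in late]
        if method == "trast_vs1":
            return trast_v1(ed, ld, fw=fusion, input_side=side)
        return trast_v2(ed, ld, input_side=side)

    if method in ("cgfm_vs1", "cgfm_vs2", "cgfm_weighted"):
        tfs, cam, tgt = cgfm_branches(model, x, target_class=target_class)
        cfg = CgfmConfig(variant=method.removeprefix("cgfm_"), alpha=cgfm_alpha)
        return cgfm(tfs, cam, cfg, target_class=tgt)

    raise ValueError(f"unknown method {method!r}; choose from {METHOD_IDS}")


def compute_all(model: ClassifierModel, x: np.ndarray, **kw) -> dict:
    """All twelve variants for one image."""
    return {m: compute_heatmap(model, x, m, **kw) for m in METHOD_IDS}
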