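"""CAM-family attributions adapted to a windowed-attention backbone.

Grad-CAM, Grad-CAM++ and HiRes-CAM operate on a captured activation tensor
and the gradient of the target-class logit with respect to it; Score-CAM
perturbs the input with activation-derived masks; Eigen-CAM takes the first
principal component of the flattened activation.  On a pure transformer
backbone there is no convolutional feature map, so the target layer resolves
to the final layer-norm token grid transposed to channel-major C x H x W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import CaptureSpec, ClassifierModel, forward_with_capture
from .postprocess import minmax_norm, upsample_bilinear

__all__ = [
    "TargetLayerAddress",
    "RawAttribution",
    "resolve_target_layer",
    "gradient_cam",
    "score_cam",
    "eigen_cam",
]


@dataclass(frozen=True)
class TargetLayerAddress:
    kind: str  # "last_conv" or "final_norm_tokens"
    grid: tuple[int, int]
    channels: int


@dataclass
class RawAttribution:
    """Unnormalised nonnegative H x W relevance on the target-layer grid."""

    values: np.ndarray
    method_id: str
    target_class: int | str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution contains non-finite values")


def resolve_target_layer(model) -> TargetLayerAddress:
    """Backbone-aware target-layer search.

    Prefers the last convolutional feature map when the model exposes one
    (`last_conv_shape` attribute); otherwise falls back to the final
    normalisation token grid of the transformer.
    """
    conv = getattr(model, "last_conv_shape", None)
    if conv is not None:
        C, H, W = conv
        return TargetLayerAddress("last_conv", (H, W), C)
    if isinstance(model, ClassifierModel):
        side = model.spec.grid_side(model.spec.n_stages - 1)
        return TargetLayerAddress("final_norm_tokens", (side, side), model.spec.embed_dims[-1])
    raise ValueError("model exposes no spatial representation for CAM")


def gradient_cam(variant: str, A: np.ndarray, G: np.ndarray,
                 target_class: int | str = "agnostic") -> RawAttribution:
    """Gradient-weighted CAM variants on channel-major activations.

    gradcam:    w_c = spatial mean of G_c;      map = ReLU(sum_c w_c A_c)
    gradcampp:  alpha-weighted rectified gradients (closed form with the
                exponential-score assumption, 0/0 -> 0)
    hirescam:   map = ReLU(sum_c A_c * G_c)  (no gradient averaging)
    """
    A = np.asarray(A, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if A.shape != G.shape or A.ndim != 3:
        raise ValueError("activations and gradients must share a C x H x W shape")
    if variant == "gradcam":
        w = G.mean(axis=(1, 2))
        m = np.einsum("c,chw->hw", w, A)
        m = np.maximum(m, 0.0)
    elif variant == "gradcampp":
        sumA = A.sum(axis=(1, 2), keepdims=True)
        num = G**2
        den = 2.0 * G**2 + sumA * G**3
        alpha = np.divide(num, den, out=np.zeros_like(num), where=np.abs(den) > 1e-12)
        w = (alpha * np.maximum(G, 0.0)).sum(axis=(1, 2))
        m = np.maximum(np.einsum("c,chw->hw", w, A), 0.0)
    elif variant == "hirescam":
        m = np.maximum((A * G).sum(axis=0), 0.0)
    else:
        raise ValueError(f"unknown CAM variant {variant!r}")
    return RawAttribution(m, variant, target_class)


def eigen_cam(A: np.ndarray) -> RawAttribution:
    """First principal spatial component of the flattened activation.

    The (H*W) x C matrix is decomposed by SVD; the first left singular
    vector scaled by its singular value gives the spatial map.  The sign is
    fixed so the map sums to >= 0, then negatives are clipped.  Class-agnostic.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 3:
        raise ValueError("expected C x H x W activations")
    C, H, W = A.shape
    M = A.reshape(C, H * W).T  # (HW, C)
    if not np.any(M):
        return RawAttribution(np.zeros((H, W)), "eigencam", "agnostic")
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    m = U[:, 0] * S[0]
    if m.sum() < 0:
        m = -m
    return RawAttribution(np.maximum(m, 0.0).reshape(H, W), "eigencam", "agnostic")


def _final_norm_activation(model: ClassifierModel, x: np.ndarray,
                           target_class: int | str, want_gradients: bool):
    spec = CaptureSpec(final_norm=True, target_activation=True,
                       want_gradients=want_gradients)
    return forward_with_capture(model, x, spec, target_class=target_class)


def score_cam(
    model: ClassifierModel,
    x: np.ndarray,
    target_class: int | str = "predicted",
    k: int = 64,
    renormalize_gated: bool = False,
) -> RawAttribution:
    """Perturbation-based CAM restricted to the k highest-variance channels.

    Each selected channel's activation is upsampled to the input size,
    min-max normalised to a unit mask, and used to multiplicatively gate the
    input; the channel weight is the target-class softmax probability of the
    gated input.  Map = ReLU(sum of weighted activations).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 4:
        x = x[0]
    bundle = _final_norm_activation(model, x, target_class, want_gradients=False)
    A = bundle.activation.activation  # (C, H, W)
    tgt = bundle.target_class
    C = A.shape[0]
    var = A.reshape(C, -1).var(axis=1)
    sel = np.sort(np.argsort(var)[::-1][: min(k, C)])
    side = x.shape[-1]
    weights = np.zeros(len(sel))
    for i, c in enumerate(sel):
        mask = minmax_norm(upsample_bilinear(A[c], side))
        gated = x * mask[None, :, :]
        if renormalize_gated:
            from .preprocess import IMAGENET_MEAN, IMAGENET_STD

            gray = np.clip(gated[0] * IMAGENET_STD[0] + IMAGENET_MEAN[0], 0.0, 1.0)
            gated = (gray[None] - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
        weights[i] = model.predict_proba(gated[None])[0, tgt]
    m = np.maximum(np.einsum("c,chw->hw", weights, A[sel]), 0.0)
    return RawAttribution(m, "scorecam", tgt)
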