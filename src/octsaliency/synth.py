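"""Deterministic synthetic fixtures: layered B-scans, a tiny backbone, ratings.

The B-scan generator draws a curved stack of alternating-reflectivity
retinal bands over a dark background with multiplicative speckle, and adds a
geometric caricature of one class-specific lesion: a subretinal
hyperreflective wedge (CNV), a dome-shaped hyporeflective detachment (CSR),
round intraretinal cysts (DME), small bumps on the bright outer band
(DRUSEN), a full-thickness central gap (MH) or nothing (NORMAL).  The rating
simulator draws 0-4 Likert scores from a latent Gaussian model with method,
rater and image effects cut at fixed thresholds.  Every generator is a pure
function of its config; random streams are counter-based per field so adding
one field never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import BackboneSpec, ClassifierModel, build_model
from .preprocess import CLASSES, RawImage, harmonize, standardize, to_model_input

__all__ = [
    "SynthOctConfig",
    "RatingSimConfig",
    "synth_oct",
    "make_dataset",
    "tiny_backbone",
    "synth_ratings",
]

_LAYER_INTENSITY = (0.80, 0.35, 0.55, 0.25, 0.60, 0.92)  # inner to outer band


@dataclass
class SynthOctConfig:
    side: int = 256
    n_layers: int = 6
    lesion_class: str = "NORMAL"
    speckle_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.side < 32:
            raise ValueError("side must be >= 32")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if self.lesion_class not in CLASSES:
            raise ValueError(f"unknown class {self.lesion_class!r}")


def _band_template(cfg: SynthOctConfig, rng: np.random.Generator):
    """Smooth curved retina band; returns (image, y_top, y_bot) arrays."""
    S = cfg.side
    x = np.arange(S)
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.02, 0.05) * S
    y_top = 0.32 * S + amp * np.sin(2 * np.pi * x / S + phase)
    thickness = rng.uniform(0.28, 0.33) * S
    y_bot = y_top + thickness
    rows = np.arange(S)[:, None].astype(np.float64)
    frac = (rows - y_top[None, :]) / thickness
    img = np.full((S, S), 0.03)
    inside = (frac >= 0) & (frac < 1)
    layer_idx = np.clip((frac * cfg.n_layers).astype(int), 0, cfg.n_layers - 1)
    intens = np.resize(np.array(_LAYER_INTENSITY), cfg.n_layers)
    img[inside] = intens[layer_idx[inside]]
    below = frac >= 1
    img[below] = 0.12 * np.exp(-(frac[below] - 1) * 6.0)  # choroid falloff
    return img, y_top, y_bot


def _apply_lesion(img: np.ndarray, cls: str, y_top: np.ndarray,
                  y_bot: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    S = img.shape[0]
    rows = np.arange(S)[:, None].astype(np.float64)
    cols = np.arange(S)[None, :].astype(np.float64)
    xc = rng.uniform(0.35, 0.65) * S

    if cls == "CNV":
        # bright subretinal wedge breaking through beneath the outer band
        half_w = rng.uniform(0.10, 0.16) * S
        depth = rng.uniform(0.12, 0.18) * S
        ybase = y_bot[None, :]
        tri = 1.0 - np.abs(cols - xc) / half_w
        mask = (tri > 0) & (rows >= ybase - 0.05 * S) & (rows <= ybase + depth * np.clip(tri, 0, 1))
        img[mask] = 0.88
    elif cls == "CSR":
        # dark fluid dome lifting the band off the bright outer line
        a = rng.uniform(0.18, 0.26) * S  # half-width
        b = rng.uniform(0.10, 0.15) * S  # height
        ybase = y_bot[None, :]
        ell = ((cols - xc) / a) ** 2 + ((rows - ybase) / b) ** 2
        mask = (ell < 1.0) & (rows < ybase)
        img[mask] = 0.05
    elif cls == "DME":
        # several round hyporeflective cysts inside the band
        n_cysts = rng.integers(2, 4)
        for _ in range(n_cysts):
            cx = rng.uniform(0.2, 0.8) * S
            j = int(np.clip(cx, 0, S - 1))
            cy = rng.uniform(0.35, 0.75) * (y_bot[j] - y_top[j]) + y_top[j]
            r = rng.uniform(0.05, 0.08) * S
            mask = (cols - cx) ** 2 + (rows - cy) ** 2 < r**2
            img[mask] = 0.06
    elif cls == "DRUSEN":
        # train of bumps undulating the bright outer band
        freq = rng.integers(6, 10)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.035, 0.055) * S
        prof = amp * np.abs(np.sin(freq * np.pi * cols[0] / S + phase))
        ybase = y_bot[None, :]
        mask = (rows >= ybase - prof[None, :]) & (rows <= ybase + 0.02 * S)
        img[mask] = 0.95
    elif cls == "MH":
        # full-thickness V-shaped gap at the centre of the band
        half_w = rng.uniform(0.06, 0.10) * S
        frac = (rows - y_top[None, :]) / (y_bot - y_top)[None, :]
        width = half_w * (0.35 + 0.65 * np.clip(frac, 0, 1))  # narrower at top
        mask = (np.abs(cols - xc) < width) & (frac >= 0) & (frac < 1)
        img[mask] = 0.03
    return img


def synth_oct(cfg: SynthOctConfig) -> RawImage:
    """One synthetic B-scan; bit-identical for identical configs."""
    rng_layout = np.random.default_rng([cfg.seed, 101])
    rng_lesion = np.random.default_rng([cfg.seed, 102])
    rng_speckle = np.random.default_rng([cfg.seed, 103])
    img, y_top, y_bot = _band_template(cfg, rng_layout)
    img = _apply_lesion(img, cfg.lesion_class, y_top, y_bot, rng_lesion)
    if cfg.speckle_sigma > 0:
        noise = rng_speckle.normal(0.0, cfg.speckle_sigma, size=img.shape)
        img = img * np.exp(noise - cfg.speckle_sigma**2 / 2)
    img = np.clip(img, 0.0, 1.0)
    return RawImage(img, source_id=f"synth-{cfg.lesion_class}-{cfg.seed}",
                    diagnosis=cfg.lesion_class)


def make_dataset(
    n_per_class: int,
    side: int = 32,
    seed: int = 0,
    speckle_sigma: float = 0.15,
    apply_clahe: bool = False,
    gen_side: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-ready (N, 3, side, side) inputs and integer labels, class-balanced.

    Each scan is rendered at `gen_side` (default twice the target side, so
    lesion primitives are resolved before downsampling, as with native-
    resolution clinical scans), letterboxed to `side`, harmonised with the
    percentile normalisation step, and ImageNet-normalised.
    """
    gen_side = gen_side or 2 * side
    xs, ys = [], []
    for ci, cls in enumerate(CLASSES):
        for i in range(n_per_class):
            cfg = SynthOctConfig(side=gen_side, lesion_class=cls,
                                 speckle_sigma=speckle_sigma,
                                 seed=seed * 1_000_003 + ci * 10_007 + i)
            std = standardize(synth_oct(cfg), target_side=side)
            std = harmonize(std, apply_clahe=apply_clahe)
            xs.append(to_model_input(std).channels)
            ys.append(ci)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def tiny_backbone(seed: int = 0, n_classes: int = 6) -> ClassifierModel:
    """Miniature windowed-attention classifier exposing every capture point:
    2 stages of depth 2, dims (16, 32), window 4 with alternating shift 0/2,
    patch 4, input 32."""
    return build_model(BackboneSpec(), n_classes=n_classes, seed=seed)


def fixture_train_config(**overrides) -> "TrainConfig":
    """From-scratch training protocol for the tiny fixture.

    The fixture backbone is randomly initialised, so it uses a single
    uniform learning rate (1.5e-3) instead of the conservative
    transfer-learning rates appropriate for a pretrained backbone.
    """
    from .training import TrainConfig

    defaults = dict(
        lr_backbone=1.5e-3,
        lr_head=1.5e-3,
        max_epochs=40,
        min_epochs=10,
        early_stop_patience=10,
        plateau_patience=4,
        batch_size=32,
        seed=56,
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclass
class RatingSimConfig:
    """Latent-Gaussian ordinal rating model over a balanced design.

    Defaults emulate the main-form study conditions: 21 raters in three
    professional groups, 10 image sets over the five disease classes, and
    latent method shifts calibrated to the observed mean ratings
    (TRAST highest, Grad-CAM++ intermediate, CGFM lowest).
    """

    n_raters: int = 21
    n_image_sets: int = 10
    method_effects: dict[str, float] = field(
        default_factory=lambda: {"TRAST": 0.55, "Grad-CAM++": -0.37, "CGFM": -0.66}
    )
    rater_sd: float = 0.5
    image_sd: float = 0.5
    noise_sd: float = 1.0
    thresholds: tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)
    form: str = "main"
    seed: int = 0

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


_SET_DIAGNOSES = ("CNV", "CSR", "DME", "DRUSEN", "MH")
RATER_GROUP_CYCLE = ("retina", "general", "resident")


def synth_ratings(cfg: RatingSimConfig) -> pd.DataFrame:
    """Balanced rating table: every rater x image set x method cell filled."""
    methods = list(cfg.method_effects)
    rng_rater = np.random.default_rng([cfg.seed, 201])
    rng_image = np.random.default_rng([cfg.seed, 202])
    rng_noise = np.random.default_rng([cfg.seed, 203])
    rater_off = cfg.rater_sd * rng_rater.standard_normal(cfg.n_raters)
    image_off = cfg.image_sd * rng_image.standard_normal(cfg.n_image_sets)
    eff = np.array([cfg.method_effects[m] for m in methods])
    noise = cfg.noise_sd * rng_noise.standard_normal(
        (cfg.n_raters, cfg.n_image_sets, len(methods))
    )
    latent = (
        eff[None, None, :]
        + rater_off[:, None, None]
        + image_off[None, :, None]
        + noise
    )
    thr = np.asarray(cfg.thresholds)
    scores = (latent[..., None] > thr).sum(axis=-1)

    groups = [RATER_GROUP_CYCLE[r % 3] for r in range(cfg.n_raters)]
    rows = []
    for r in range(cfg.n_raters):
        for i in range(cfg.n_image_sets):
            diag = _SET_DIAGNOSES[i % len(_SET_DIAGNOSES)]
            for j, m in enumerate(methods):
                rows.append(
                    (f"rater{r:02d}", groups[r], cfg.form, i + 1, diag, m,
                     int(scores[r, i, j]))
                )
    return pd.DataFrame(rows, columns=["rater_id", "group", "form", "image_set",
                                       "diagnosis", "method", "score"])
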