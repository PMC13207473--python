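"""OCT B-scan preprocessing: letterboxing, contrast harmonisation, model input.

The pipeline converts arbitrary grayscale (or RGB) B-scans into a fixed
256x256 unit-interval representation: aspect-ratio-preserving Lanczos resize
with centred zero padding, CLAHE contrast harmonisation followed by robust
2nd/98th-percentile intensity normalisation, and replication to three
ImageNet-normalised channels.  Training-time augmentation (flip, rotation,
affine jitter, brightness/contrast, gamma, blur) is fully seeded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure, transform as sktransform

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

CLASSES = ("CNV", "CSR", "DME", "DRUSEN", "MH", "NORMAL")

# ITU-R BT.601 luma weights for collapsing RGB inputs
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageError(ValueError):
    """Raised for degenerate or non-finite input images."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class LetterboxRecord:
    """Where the resized content sits inside the square frame."""

    scale: float
    row_offset: int
    col_offset: int
    rows: int
    cols: int
    pad_value: float = 0.0


@dataclass
class RawImage:
    """Native-resolution B-scan plus provenance."""

    pixels: np.ndarray
    source_id: str = ""
    diagnosis: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ImageError("expected a 2D grayscale or 3D multichannel array")
        h, w = self.pixels.shape[:2]
        if h < 8 or w < 8:
            raise ImageError(f"image too small: {h}x{w} (minimum side 8)")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=np.float64))):
            raise ImageError("non-finite pixel values")
        if self.diagnosis is not None and self.diagnosis not in CLASSES:
            raise ImageError(f"unknown diagnosis label {self.diagnosis!r}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class StandardImage:
    """256x256 unit-interval grayscale frame with its letterbox record."""

    gray: np.ndarray
    letterbox: LetterboxRecord

    def __post_init__(self):
        self.gray = np.asarray(self.gray, dtype=np.float64)
        if self.gray.ndim != 2 or self.gray.shape[0] != self.gray.shape[1]:
            raise ImageError("StandardImage must be square 2D")


@dataclass
class ModelInput:
    """Three ImageNet-normalised channels derived from one grayscale plane."""

    channels: np.ndarray  # (3, side, side)
    mean: np.ndarray = field(default_factory=lambda: IMAGENET_MEAN.copy())
    std: np.ndarray = field(default_factory=lambda: IMAGENET_STD.copy())


@dataclass
class AugmentConfig:
    flip_p: float = 0.5
    max_rotation_deg: float = 15.0
    max_translate_frac: float = 0.03
    scale_range: tuple[float, float] = (0.89, 1.15)
    brightness_contrast_jitter: float = 0.3
    gamma_range: tuple[float, float] = (0.8, 1.2)
    gamma_p: float = 0.7
    blur_kernel: int = 3
    blur_p: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for p in (self.flip_p, self.gamma_p, self.blur_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale_range must be increasing")


def to_gray_unit(pixels: np.ndarray) -> np.ndarray:
    """Collapse channels (BT.601) and rescale to [0,1] by native bit depth."""
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = np.tensordot(arr[:, :, :3].astype(np.float64), _LUMA, axes=([2], [0]))
    if np.issubdtype(np.asarray(pixels).dtype, np.integer):
        maxval = float(np.iinfo(np.asarray(pixels).dtype).max)
        arr = arr.astype(np.float64) / maxval
    else:
        arr = arr.astype(np.float64)
    return np.clip(arr, 0.0, 1.0)


def standardize(raw: RawImage, target_side: int = 256) -> StandardImage:
    """Aspect-preserving Lanczos letterbox into a zero-padded square frame.

    The longer raw dimension maps to `target_side`; the shorter one is scaled
    by the same factor (extent rounded half-up) and centred, with any odd
    padding pixel going to the bottom/right.
    """
    if target_side < 8:
        raise ImageError("target_side must be >= 8")
    gray = to_gray_unit(raw.pixels)
    h, w = gray.shape
    scale = target_side / max(h, w)
    rows = min(target_side, max(1, _round_half_up(h * scale)))
    cols = min(target_side, max(1, _round_half_up(w * scale)))
    resized = np.asarray(
        Image.fromarray(gray.astype(np.float32), mode="F").resize(
            (cols, rows), resample=Image.LANCZOS
        ),
        dtype=np.float64,
    )
    resized = np.clip(resized, 0.0, 1.0)  # Lanczos ringing can overshoot
    row_off = (target_side - rows) // 2
    col_off = (target_side - cols) // 2
    frame = np.zeros((target_side, target_side), dtype=np.float64)
    frame[row_off : row_off + rows, col_off : col_off + cols] = resized
    return StandardImage(frame, LetterboxRecord(scale, row_off, col_off, rows, cols))


def harmonize(
    std: StandardImage,
    clip_limit: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
    p_low: float = 2.0,
    p_high: float = 98.0,
    apply_clahe: bool = True,
    tol: float = 1e-9,
) -> StandardImage:
    """CLAHE then robust percentile normalisation.

    CLAHE runs on the 8-bit quantisation of the full letterboxed frame
    (clip limit expressed in OpenCV convention, converted to scikit-image's
    normalised fraction as clip/256).  The result is clipped to its own
    [P2, P98] range and affinely rescaled so P2 -> 0 and P98 -> 1.
    """
    gray = std.gray
    if apply_clahe:
        quant = np.floor(gray * 255.0).astype(np.uint8)
        side = gray.shape[0]
        kernel = (max(1, side // tiles[0]), max(1, gray.shape[1] // tiles[1]))
        gray = exposure.equalize_adapthist(
            quant, kernel_size=kernel, clip_limit=clip_limit / 256.0
        )
    lo, hi = np.percentile(gray, [p_low, p_high])
    if hi - lo < tol:
        warnings.warn("degenerate percentile range; returning all-zero image")
        return StandardImage(np.zeros_like(gray), std.letterbox)
    out = np.clip((gray - lo) / (hi - lo), 0.0, 1.0)
    return StandardImage(out, std.letterbox)


def to_model_input(std: StandardImage) -> ModelInput:
    """Replicate the grayscale plane to three ImageNet-normalised channels."""
    chans = (std.gray[None, :, :] - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
    return ModelInput(chans)


def from_model_input(mi: ModelInput) -> np.ndarray:
    """Invert :func:`to_model_input` (recovers the grayscale plane)."""
    return mi.channels[0] * mi.std[0] + mi.mean[0]


def augment(std: StandardImage, cfg: AugmentConfig) -> StandardImage:
    """Seeded stochastic augmentation in the fixed order: flip, rotation,
    affine translate/scale, brightness/contrast jitter, gamma, blur."""
    rng = np.random.default_rng(cfg.seed)
    img = std.gray.copy()
    side = img.shape[0]

    if rng.random() < cfg.flip_p:
        img = img[:, ::-1].copy()

    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
    if angle != 0.0:
        img = sktransform.rotate(img, angle, order=1, mode="constant", cval=0.0)

    tx = rng.uniform(-cfg.max_translate_frac, cfg.max_translate_frac) * side
    ty = rng.uniform(-cfg.max_translate_frac, cfg.max_translate_frac) * side
    sc = rng.uniform(cfg.scale_range[0], cfg.scale_range[1])
    if tx != 0.0 or ty != 0.0 or sc != 1.0:
        centre = (side - 1) / 2.0
        tf = (
            sktransform.AffineTransform(translation=(-centre, -centre))
            + sktransform.AffineTransform(scale=(sc, sc))
            + sktransform.AffineTransform(translation=(centre + tx, centre + ty))
        )
        img = sktransform.warp(img, tf.inverse, order=1, mode="constant", cval=0.0)

    j = cfg.brightness_contrast_jitter
    if j > 0:
        img = img * rng.uniform(1 - j, 1 + j)  # brightness
        f = rng.uniform(1 - j, 1 + j)  # contrast about the mean
        img = img.mean() + f * (img - img.mean())
        img = np.clip(img, 0.0, 1.0)

    if rng.random() < cfg.gamma_p:
        gamma = rng.uniform(*cfg.gamma_range)
        img = np.clip(img, 0.0, 1.0) ** gamma

    if rng.random() < cfg.blur_p:
        sigma = rng.uniform(0.1, 2.0)
        radius = cfg.blur_kernel // 2
        img = ndimage.gaussian_filter(img, sigma=sigma, truncate=radius / sigma)

    return StandardImage(np.clip(img, 0.0, 1.0), std.letterbox)


# ---------------------------------------------------------------------- I/O
def read_image(path: str | Path, diagnosis: str | None = None) -> RawImage:
    """Read PNG/TIFF/JPEG (8/16-bit, gray or RGB) into a RawImage."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    return RawImage(arr, source_id=Path(path).name, diagnosis=diagnosis)


def write_standard(std: StandardImage, path: str | Path) -> None:
    """Write a standardized image as 16-bit PNG plus a JSON letterbox sidecar."""
    path = Path(path)
    arr16 = np.round(np.clip(std.gray, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(arr16, mode="I;16").save(path)
    path.with_suffix(".json").write_text(json.dumps(asdict(std.letterbox)))


def read_standard(path: str | Path) -> StandardImage:
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64) / 65535.0
    rec = LetterboxRecord(**json.loads(path.with_suffix(".json").read_text()))
    return StandardImage(arr, rec)
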