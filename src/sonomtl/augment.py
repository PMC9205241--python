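"""RoI extraction and training-time stochastic augmentation.

Training images are cropped to the annotated box (plus a context
margin), then augmented with random scale-cropping, horizontal flips
and photometric (brightness/contrast) jitter — the grayscale analogue
of color distortion — and finally resized to the model input size.
Evaluation applies the resize only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from sonomtl.dataio import ImageRecord
from sonomtl.errors import ConfigurationError, DataError


@dataclass
class AugmentConfig:
    crop_scale_range: tuple[float, float] = (0.8, 1.0)  # area fraction of the crop
    flip_prob: float = 0.5
    brightness_jitter: float = 0.2
    contrast_jitter: float = 0.2
    output_size: int = 256
    train_mode: bool = True
    interpolation: str = "bilinear"  # or "nearest"

    def validate(self) -> "AugmentConfig":
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(f"crop_scale_range must be within (0,1], got {self.crop_scale_range}")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ConfigurationError(f"flip_prob must be a probability, got {self.flip_prob}")
        if self.brightness_jitter < 0 or self.contrast_jitter < 0:
            raise ConfigurationError("jitter fractions must be nonnegative")
        if self.output_size <= 0:
            raise ConfigurationError(f"output_size must be positive, got {self.output_size}")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ConfigurationError(f"unknown interpolation {self.interpolation!r}")
        return self


def extract_roi(record: ImageRecord, context_margin: float = 0.0) -> np.ndarray:
    """Crop the record's box expanded by ``context_margin`` per side, clipped.

    The margin is a fraction of the box width (height) added on each
    horizontal (vertical) side.
    """
    x0, y0, x1, y1 = record.box
    if x1 <= x0 or y1 <= y0:
        raise DataError(f"{record.image_id}: degenerate box {record.box}")
    h, w = record.pixels.shape
    mx = int(round((x1 - x0) * context_margin))
    my = int(round((y1 - y0) * context_margin))
    cx0, cy0 = max(0, x0 - mx), max(0, y0 - my)
    cx1, cy1 = min(w, x1 + mx), min(h, y1 + my)
    return record.pixels[cy0:cy1, cx0:cx1]


def _resize(image: np.ndarray, size: int, interpolation: str) -> np.ndarray:
    if image.shape == (size, size):
        return image.astype(float)
    order = 1 if interpolation == "bilinear" else 0
    return resize(image.astype(float), (size, size), order=order,
                  preserve_range=True, anti_aliasing=False)


def augment(image: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply the augmentation pipeline; returns a float array in [0, 255].

    Train mode: random scale-crop → horizontal flip → brightness/contrast
    jitter → resize.  Eval mode (``train_mode=False``): resize only.
    Deterministic given ``rng``.
    """
    cfg.validate()
    if image.size == 0:
        raise DataError("cannot augment an empty image")
    img = image.astype(float)
    if cfg.train_mode:
        if rng is None:
            raise ConfigurationError("train-mode augmentation requires an rng")
        h, w = img.shape
        area = rng.uniform(*cfg.crop_scale_range)
        side = float(np.sqrt(area))
        ch, cw = max(1, int(round(h * side))), max(1, int(round(w * side)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        img = img[top:top + ch, left:left + cw]
        if rng.random() < cfg.flip_prob:
            img = img[:, ::-1]
        b = rng.uniform(1.0 - cfg.brightness_jitter, 1.0 + cfg.brightness_jitter)
        c = rng.uniform(1.0 - cfg.contrast_jitter, 1.0 + cfg.contrast_jitter)
        img = img * b
        img = (img - img.mean()) * c + img.mean()
        img = np.clip(img, 0.0, 255.0)
    out = _resize(img, cfg.output_size, cfg.interpolation)
    return np.clip(out, 0.0, 255.0)
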