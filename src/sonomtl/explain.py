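"""Grad-CAM heatmaps per task head and radial response profiles.

Grad-CAM weights each channel of a convolutional stage's activation map
by the global-average-pooled gradient of the head's pre-sigmoid output
with respect to that map, sums, rectifies, upsamples bilinearly to the
input size and normalizes by the maximum (an identically zero map stays
zero).  The radial profile averages heatmap values in equal-width
annuli around the image center out to half the image diagonal — a
summary of how much central (intratumoral) versus peripheral context
drives a head's prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize

from sonomtl.errors import ConfigurationError
from sonomtl.model import MultiTaskModel


@dataclass
class Heatmap:
    values: np.ndarray  # 2-D array in [0, 1], input-image resolution
    task: str


def grad_cam(model: MultiTaskModel, image: np.ndarray, task_head: str,
             target_layer: int | None = None) -> Heatmap:
    """Grad-CAM heatmap of one head on one image (eval mode).

    ``target_layer`` indexes the backbone stage (0 = stem output,
    higher = deeper); default is the last convolutional stage before
    pooling.
    """
    if task_head not in model.tasks:
        raise ConfigurationError(f"model has no head {task_head!r}; heads: {model.tasks}")
    n_stages = len(model.backbone.blocks) + 1
    if target_layer is None:
        target_layer = n_stages - 1
    if not (0 <= target_layer < n_stages):
        raise ConfigurationError(f"target_layer must be in [0, {n_stages - 1}], got {target_layer}")

    img = np.asarray(image, dtype=float)
    model.forward_arrays(img[None], train=False)
    activations = model.backbone.stage_outputs[target_layer]  # (1, C, h, w)

    # d(pre-sigmoid head output)/d(pooled features) is the head weight row
    head = model.heads[task_head]
    dfeat = head.W.astype(activations.dtype)  # (1, feature_dim)
    model.zero_grad()
    grads = model.backbone.backward(dfeat, stop_at_stage=target_layer)

    alpha = grads.mean(axis=(2, 3))[0]  # GAP of gradients, per channel
    cam = np.maximum(0.0, np.tensordot(alpha, activations[0], axes=1))
    cam = resize(cam, img.shape, order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, task=task_head)


def radial_profile(h: Heatmap | np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Mean heatmap response per distance-to-center annulus.

    Bins are equal-width in radius from 0 to half the image diagonal;
    empty bins are NaN.
    """
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    values = h.values if isinstance(h, Heatmap) else np.asarray(h, dtype=float)
    hh, ww = values.shape
    cy, cx = (hh - 1) / 2.0, (ww - 1) / 2.0
    yy, xx = np.mgrid[0:hh, 0:ww]
    dist = np.hypot(yy - cy, xx - cx)
    r_max = np.hypot(hh, ww) / 2.0
    idx = np.minimum((dist / r_max * n_bins).astype(int), n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            out[b] = values[sel].mean()
    return out


def center_periphery_means(h: Heatmap | np.ndarray) -> tuple[float, float]:
    """Mean response inside vs outside half the maximal center distance."""
    values = h.values if isinstance(h, Heatmap) else np.asarray(h, dtype=float)
    hh, ww = values.shape
    cy, cx = (hh - 1) / 2.0, (ww - 1) / 2.0
    yy, xx = np.mgrid[0:hh, 0:ww]
    dist = np.hypot(yy - cy, xx - cx)
    inner = dist <= dist.max() / 2.0
    return float(values[inner].mean()), float(values[~inner].mean())


def save_overlay(image: np.ndarray, heatmap: Heatmap, path: str | Path,
                 alpha: float = 0.5) -> None:
    """Write the heatmap over the grayscale image with a blue-to-red colormap."""
    gray = np.asarray(image, dtype=float) / 255.0
    rgb_img = np.stack([gray] * 3, axis=-1)
    rgb_cam = colormaps["jet"](heatmap.values)[..., :3]
    blend = np.clip((1 - alpha) * rgb_img + alpha * rgb_cam, 0.0, 1.0)
    Image.fromarray((blend * 255).astype(np.uint8)).save(Path(path))
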