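"""GradCAM attribution for the image classifier.

For a chosen target class, the gradient of that class's pre-softmax
score with respect to the final convolutional layer's activations is
averaged over space to give one weight per channel; the rectified
(negative values zeroed) weighted sum of the activation channels is the
raw class-activation map. It is upsampled bilinearly to image resolution
and divided by its maximum (all-zero maps are flagged instead), then
rendered as a blue-to-red overlay or integrated over the stacked-lead
layout to quantify how much attribution each lead strip receives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .errors import LayoutError, ShapeError, UnsupportedModelError
from .imaging import RenderConfig
from .leads import PANEL_ORDER
from .model import ImageClassifier

#: Diverging blue (low attribution) to red (high attribution) palette.
COLORMAP = "jet"


@dataclass(frozen=True)
class Heatmap:
    """GradCAM result at feature-map and image resolution."""

    raw: np.ndarray          # (h', w') non-negative, feature resolution
    upsampled: np.ndarray    # (H, W) in [0, 1], image resolution
    target_class: int
    empty: bool = False      # True when the raw map was identically zero


def _bilinear_upsample(grid: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize with half-pixel-aligned sample positions."""
    in_h, in_w = grid.shape
    ys = (np.arange(out_h) + 0.5) * in_h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * in_w / out_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, in_h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, in_w - 1)
    y1 = np.clip(y0 + 1, 0, in_h - 1)
    x1 = np.clip(x0 + 1, 0, in_w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :]
    top = grid[np.ix_(y0, x0)] * (1 - wx) + grid[np.ix_(y0, x1)] * wx
    bot = grid[np.ix_(y1, x0)] * (1 - wx) + grid[np.ix_(y1, x1)] * wx
    return top * (1 - wy) + bot * wy


def compute_gradcam(model: ImageClassifier, image: np.ndarray,
                    target_class: int) -> Heatmap:
    """Class-activation heatmap for one 8-bit image.

    Channel weights are the spatial means of d(score)/d(activation) at
    the final convolution's (post-ReLU) output; the weighted channel sum
    is rectified, upsampled and max-normalized.
    """
    if not hasattr(model, "gradcam_layer_index"):
        raise UnsupportedModelError(
            "model does not expose a convolutional attribution layer")
    if target_class not in (0, 1):
        raise ShapeError(f"target_class must be 0 or 1, got {target_class}")
    x = model.prepare(np.asarray(image))
    layers = model.net.layers
    idx = model.gradcam_layer_index

    h = x
    act = None
    for i, layer in enumerate(layers):
        h = layer.forward(h)
        if i == idx:
            act = h
    logits = h  # (1, 2)

    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    # gradient w.r.t. the output of the attribution layer = input of idx+1
    dact = model.net.backward(dlogits, down_to=idx + 1)

    weights = dact[0].mean(axis=(1, 2))            # (channels,)
    raw = np.maximum(np.tensordot(weights, act[0], axes=1), 0.0)
    img_h, img_w = np.asarray(image).shape[-2:]
    up = _bilinear_upsample(raw, img_h, img_w)
    peak = up.max()
    if peak <= 0.0:
        return Heatmap(raw=raw, upsampled=np.zeros_like(up),
                       target_class=target_class, empty=True)
    return Heatmap(raw=raw, upsampled=np.clip(up / peak, 0.0, 1.0),
                   target_class=target_class, empty=False)


def overlay(heatmap: Heatmap, image: np.ndarray,
            alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend the colormapped heatmap over the grayscale image.

    Returns an (H, W, 3) uint8 RGB image; ``alpha=0`` reproduces the
    grayscale image, ``alpha=1`` the pure colormap.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != heatmap.upsampled.shape:
        raise ShapeError(
            f"image {img.shape} vs heatmap {heatmap.upsampled.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ShapeError("alpha must lie in [0, 1]")
    cmap = colormaps[COLORMAP]
    colored = cmap(heatmap.upsampled)[:, :, :3] * 255.0
    gray_rgb = np.repeat(img[:, :, None], 3, axis=2)
    blended = (1.0 - alpha) * gray_rgb + alpha * colored
    return np.clip(np.floor(blended + 0.5), 0, 255).astype(np.uint8)


def strip_attribution(heatmap: Heatmap, config: RenderConfig | None = None,
                      n_time_bins: int = 1) -> dict:
    """Integrate attribution mass over the stacked-lead layout.

    Returns per-lead shares of the total heatmap mass (gap rows count
    toward the total but belong to no lead, so the shares sum to <= 1)
    and a (lead, time-bin) share matrix.
    """
    config = config or RenderConfig()
    up = heatmap.upsampled
    bands = config.strip_row_bands()
    if up.shape[0] < bands[-1][1]:
        raise LayoutError(
            f"heatmap height {up.shape[0]} shorter than layout "
            f"({bands[-1][1]} rows)")
    total = float(up.sum())
    n_cols = up.shape[1]
    edges = np.linspace(0, n_cols, n_time_bins + 1).astype(int)
    lead_shares: dict[str, float] = {}
    matrix = np.zeros((len(PANEL_ORDER), n_time_bins))
    for li, (name, (start, stop)) in enumerate(zip(PANEL_ORDER, bands)):
        band = up[start:stop, :]
        lead_shares[name] = float(band.sum() / total) if total > 0 else 0.0
        for b in range(n_time_bins):
            chunk = band[:, edges[b]:edges[b + 1]]
            matrix[li, b] = chunk.sum() / total if total > 0 else 0.0
    return {"lead_shares": lead_shares, "time_bin_shares": matrix,
            "leads": list(PANEL_ORDER), "empty": heatmap.empty}
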