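"""Grad-CAM: class-discriminative heat maps from the last conv block.

The map for a target class is the ReLU of the channel-weighted sum of
the last convolutional block's activation maps, where each channel's
weight is the spatial mean of the gradient of the class's pre-softmax
score with respect to that map.  Gradients are taken against the
pre-softmax score (softmax gradients saturate); the hook sits at the
third block's activation output — the last spatial representation
before pooling feeds the fully connected head.  The map is upsampled
bilinearly to the input size and min–max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from . import _nn

__all__ = ["Heatmap", "grad_cam", "save_overlay"]


class ExplainError(ValueError):
    pass


@dataclass
class Heatmap:
    """Normalized relevance map aligned to the input image.

    ``all_zero`` flags the degenerate case where the raw rectified map
    is identically zero (nothing supports the class); the values are
    then all zeros rather than an arbitrary normalization.
    """

    values: np.ndarray
    target_class: int
    all_zero: bool = False


def _last_activation_index(model: _nn.Model) -> int:
    idx = [i for i, layer in enumerate(model.layers)
           if isinstance(layer, _nn.Activation)]
    if not idx:
        raise ExplainError("model has no activation layers to hook")
    return idx[-1]


def grad_cam(model: _nn.Model, image: np.ndarray, target_class: int) -> Heatmap:
    """Compute the Grad-CAM heat map of ``target_class`` for one image."""
    if not 0 <= target_class < model.num_classes:
        raise ExplainError(
            f"target_class {target_class} out of range [0, {model.num_classes})")
    x = np.asarray(image, np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != tuple(model.input_shape):
        raise ExplainError(
            f"image shape {x.shape[1:]} does not match model input "
            f"{tuple(model.input_shape)}")
    hook = _last_activation_index(model)
    logits = model.forward(x, train=False, capture=True)
    fmap = model.captured_output(hook)[0]            # (h, w, C)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = model.grad_wrt_layer(hook, dlogits)[0]    # (h, w, C)
    weights = grad.mean(axis=(0, 1))                 # spatial-mean channel weights
    raw = np.maximum((fmap * weights).sum(axis=-1), 0.0)
    in_h, in_w = model.input_shape[:2]
    if raw.max() <= 0:
        return Heatmap(np.zeros((in_h, in_w), np.float32), target_class, all_zero=True)
    up = zoom(raw, (in_h / raw.shape[0], in_w / raw.shape[1]), order=1)
    up = np.clip(up, 0.0, None)
    up = (up - up.min()) / (up.max() - up.min())
    return Heatmap(up.astype(np.float32), target_class)


def save_overlay(image: np.ndarray, heatmap: Heatmap, path,
                 alpha: float = 0.45, cmap: str = "jet") -> None:
    """Write the heat map blended over the image as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(image), interpolation="nearest")
    ax.imshow(heatmap.values, cmap=cmap, alpha=alpha, interpolation="bilinear")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0, dpi=150)
    plt.close(fig)
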