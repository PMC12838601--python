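"""Grad-CAM heat maps over the MIP inputs, with a quantitative localization
score against phantom lesion masks.

The map is taken at the final convolutional stage of the backbone (the
standard Grad-CAM tap): channel weights are the spatially averaged gradients
of the target-class logit, the map is the rectified weighted sum of feature
maps, bilinearly upsampled to the input size and max-normalized to [0, 1].
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .nn.network import MipFusionNetwork
from .preproc import project_mip, resize_pad


def _cam_from(act: np.ndarray, grad: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """act, grad: (C, h, w) for one item -> normalized (H, W) map."""
    weights = grad.mean(axis=(1, 2))  # spatially averaged gradients
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    cam = _sk_resize(cam, out_shape, order=1, preserve_range=True, anti_aliasing=False)
    cam = np.clip(cam, 0.0, None)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def gradcam(
    network: MipFusionNetwork,
    batch_item: dict,
    target_class: int = 1,
    fallback: bool = False,
) -> dict[str, np.ndarray]:
    """Heat map(s) for a single case.

    ``batch_item`` holds 'anterior' (1,H,W,3), 'lateral', 'clinical', 's'.
    The single output logit scores class 1, so the class-0 map uses the
    negated logit gradient.  Returns {view: (H, W) map in [0, 1]}.
    """
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    n = batch_item["anterior"].shape[0]
    if n != 1:
        raise ValueError("gradcam expects a single case")
    for p in network.params():
        p.zero_grad()
    network.forward(batch_item, train=False, fallback=fallback)
    dlogit = np.array([1.0 if target_class == 1 else -1.0], dtype=np.float32)
    network.backward(dlogit)
    act = network.last_conv_act
    grad = network.last_conv_grad
    if act.shape[2] < 1 or act.shape[3] < 1:
        raise ValueError("target layer has no spatial extent")
    h, w = batch_item["anterior"].shape[1:3]
    maps = {}
    if network.config.views == "both":
        maps["anterior"] = _cam_from(act[0], grad[0], (h, w))
        maps["lateral"] = _cam_from(act[1], grad[1], (h, w))
    else:
        maps["anterior"] = _cam_from(act[0], grad[0], (h, w))
    for p in network.params():
        p.zero_grad()
    return maps


def project_lesion_mask(
    mask: np.ndarray, view: str, target: int, spacing_mm=(1.0, 1.0, 1.0)
) -> np.ndarray:
    """Project the 3D lesion mask through the same MIP + resize/pad geometry
    as the images; returns a boolean (target, target) mask."""
    mip = project_mip(mask.astype(np.float64), view, spacing_mm)
    img = resize_pad(mip.pixels, target)
    return img >= 0.25  # bilinear smearing keeps thin lesions above this


def localization_score(heat_map: np.ndarray, mask_2d: np.ndarray, top_frac: float = 0.1) -> float:
    """Fraction of the hottest ``top_frac`` heat-map pixels inside the mask."""
    heat_map = np.asarray(heat_map, dtype=np.float64)
    mask_2d = np.asarray(mask_2d, dtype=bool)
    if heat_map.shape != mask_2d.shape:
        raise ValueError("map and mask shapes must match")
    if not mask_2d.any():
        raise ValueError("empty lesion mask: localization undefined")
    k = max(1, int(round(top_frac * heat_map.size)))
    flat = heat_map.ravel()
    top_idx = np.argpartition(flat, -k)[-k:]
    return float(mask_2d.ravel()[top_idx].mean())


def save_overlay_png(
    image: np.ndarray, heat_map: np.ndarray, path, alpha: float = 0.45
) -> None:
    """Write the MIP with a warm-colormap Grad-CAM overlay (warm = high)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    base = image[..., 0] if image.ndim == 3 else image
    ax.imshow(base, cmap="gray", vmin=0, vmax=1)
    ax.imshow(heat_map, cmap="jet", alpha=alpha, vmin=0, vmax=1)
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=100)
    plt.close(fig)
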