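"""Heatmap targets and the soft-argmax decoder.

Each contour point is encoded as an isotropic bivariate normal density
(peak value 1) centered on the point; the standard deviation is a fraction
of the image width so the encoding is resolution independent.  A 97th map
carries the filled mandible mask.  Decoding normalizes a map to sum 1 and
takes the probability-weighted mean of pixel coordinates — a sub-pixel,
differentiable approximation of the heatmap peak.
"""

from __future__ import annotations

import numpy as np

from .contour import MandibleContour, contour_to_mask


class DegenerateHeatmapError(ValueError):
    """A heatmap with no positive mass after rectification."""


def make_target_heatmaps(
    c: MandibleContour, hw: tuple, sigma_frac: float = 0.01
) -> np.ndarray:
    """Target stack (97, h, w): 96 Gaussian maps + the mandible mask.

    sigma in pixels is ``sigma_frac * w``. Every contour point must lie
    inside the (h, w) frame; rescale annotations to the network input size
    before calling.
    """
    height, width = hw
    if sigma_frac <= 0:
        raise ValueError("sigma_frac must be positive")
    pts = c.points
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > width - 1) or \
       np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > height - 1):
        raise ValueError(
            "contour point outside image; rescale annotations to the "
            "target heatmap size first"
        )
    sigma = sigma_frac * width
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    dx2 = (xs[None, :] - pts[:, 0, None]) ** 2      # (96, w)
    dy2 = (ys[None, :] - pts[:, 1, None]) ** 2      # (96, h)
    maps = np.exp(
        -(dy2[:, :, None] + dx2[:, None, :]) / (2.0 * sigma**2)
    )                                               # (96, h, w)
    mask = contour_to_mask(c, hw).astype(float)
    return np.concatenate([maps, mask[None]], axis=0)


def rectify(hmap: np.ndarray, threshold_frac: float = 0.0) -> np.ndarray:
    """Clamp a raw map to nonnegative values.

    With ``threshold_frac`` > 0, subtract that fraction of the map maximum
    first; for maps symmetric about their peak this leaves the decoded
    coordinate unchanged while suppressing diffuse low-level background.
    """
    hmap = np.asarray(hmap, dtype=float)
    if threshold_frac > 0:
        hmap = hmap - threshold_frac * hmap.max()
    return np.clip(hmap, 0.0, None)


def normalize_heatmap(hmap: np.ndarray) -> np.ndarray:
    """Rectify and rescale a map so its pixel values add up to 1."""
    hmap = rectify(hmap)
    total = hmap.sum()
    if total <= 0:
        raise DegenerateHeatmapError("degenerate heatmap: no positive values")
    return hmap / total


def soft_argmax(p: np.ndarray) -> tuple:
    """Probability-weighted mean pixel coordinate (x, y) of a normalized map."""
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if abs(total - 1.0) > 1e-4:
        raise ValueError(
            f"soft_argmax expects a normalized map (sum 1), got sum {total:.6g}"
        )
    h, w = p.shape
    x = float(np.arange(w) @ p.sum(axis=0))
    y = float(np.arange(h) @ p.sum(axis=1))
    return x, y


def decode_stack(
    stack: np.ndarray, threshold_frac: float = 0.0
) -> tuple:
    """Decode the 96 point maps of a (>=96, h, w) stack to coordinates.

    Returns ``(points, flagged)`` where ``flagged`` lists indices whose map
    was degenerate (those points are set to the map center).
    """
    h, w = stack.shape[-2:]
    pts = np.zeros((96, 2), dtype=float)
    flagged = []
    for i in range(96):
        try:
            p = normalize_heatmap(rectify(stack[i], threshold_frac))
            pts[i] = soft_argmax(p)
        except DegenerateHeatmapError:
            flagged.append(i)
            pts[i] = ((w - 1) / 2.0, (h - 1) / 2.0)
    return pts, flagged
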