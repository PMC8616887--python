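"""Digitization-quality metrics: point-to-point, point-to-curve, Dice.

Distances computed in pixels are converted to mm with the acquisition
resolution (11.11 px/mm for the panoramic unit this pipeline targets).
The reference "curve" for the point-to-curve error is the closed polyline
through the 96 reference points, not just the discrete points.
"""

from __future__ import annotations

import numpy as np

from .contour import MandibleContour
from .descriptors import MEASUREMENT_ORDER, measure

DEFAULT_PX_PER_MM = 11.11

#: Table rows that average the left and right sides.
BILATERAL_CODES = ("a2", "a3", "d1", "d2", "d3", "d6", "d7")


def px_to_mm(v_px, spacing: float = DEFAULT_PX_PER_MM):
    """Convert pixel distances to millimetres."""
    if spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    return v_px / spacing


def _spacing_of(*contours, spacing=None):
    if spacing is not None:
        return spacing
    spacings = {c.px_per_mm for c in contours if c.px_per_mm}
    if len(spacings) == 1:
        return spacings.pop()
    return None


def p2p_error(
    a: MandibleContour, b: MandibleContour, landmark: str, spacing=None
) -> float:
    """Euclidean distance between one named landmark in two contours.

    Returned in mm when a pixel spacing is available (argument or carried
    by both contours), otherwise in px.
    """
    d = float(np.linalg.norm(a.landmark(landmark) - b.landmark(landmark)))
    sp = _spacing_of(a, b, spacing=spacing)
    return px_to_mm(d, sp) if sp else d


def _point_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to a closed polyline (vectorized)."""
    a = poly                                  # (m, 2) segment starts
    b = np.roll(poly, -1, axis=0)             # segment ends
    ab = b - a                                # (m, 2)
    ab2 = (ab * ab).sum(axis=1)               # (m,)
    ap = points[:, None, :] - a[None, :, :]   # (n, m, 2)
    t = (ap * ab[None]).sum(axis=2) / np.where(ab2 > 0, ab2, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def pt2crv_error(
    est: MandibleContour, ref: MandibleContour, spacing=None
) -> float:
    """Mean over the 96 estimated points of the minimum distance to the
    reference contour curve. Directed (not symmetric): est -> ref."""
    d = float(_point_to_polyline(est.points, ref.points).mean())
    sp = _spacing_of(est, ref, spacing=spacing)
    return px_to_mm(d, sp) if sp else d


def dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 1.0 if both empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask size mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def measurement_errors(
    est: MandibleContour, ref: MandibleContour, spacing=None
) -> dict:
    """Absolute error of every measurement; distances in mm when possible."""
    sp = _spacing_of(est, ref, spacing=spacing)
    if sp:
        est = MandibleContour(est.points, px_per_mm=sp, scheme=est.scheme)
        ref = MandibleContour(ref.points, px_per_mm=sp, scheme=ref.scheme)
    me, mr = measure(est), measure(ref)
    return {k: abs(me.values[k] - mr.values[k]) for k in MEASUREMENT_ORDER}


def digitization_report(
    est_contours: list, ref_contours: list, spacing=DEFAULT_PX_PER_MM,
    masks_hw: tuple | None = None,
) -> dict:
    """Cohort-level digitization quality summary.

    Per-landmark point-to-point error, PT2CRV, per-measurement absolute
    errors with left/right-averaged rows for the bilateral codes, and DSC
    of the rasterized masks (when ``masks_hw`` is given), each as
    mean ± SD across image pairs.
    """
    from .contour import contour_to_mask

    if len(est_contours) != len(ref_contours):
        raise ValueError("contour lists must be paired")
    lms = list(est_contours[0].landmark_indices)
    p2p = {n: [] for n in lms}
    crv, dices = [], []
    merr = {k: [] for k in MEASUREMENT_ORDER}
    for e, r in zip(est_contours, ref_contours):
        for n in lms:
            p2p[n].append(p2p_error(e, r, n, spacing=spacing))
        crv.append(pt2crv_error(e, r, spacing=spacing))
        for k, v in measurement_errors(e, r, spacing=spacing).items():
            merr[k].append(v)
        if masks_hw is not None:
            dices.append(
                dsc(contour_to_mask(e, masks_hw), contour_to_mask(r, masks_hw))
            )

    def ms(x):
        arr = np.asarray(x, dtype=float)
        return {"mean": float(arr.mean()), "sd": float(arr.std())}

    meas = {k: ms(v) for k, v in merr.items()}
    for code in BILATERAL_CODES:
        both = np.asarray(merr[code + "L"] + merr[code + "R"], dtype=float)
        meas[code] = {"mean": float(both.mean()), "sd": float(both.std())}
    report = {
        "p2p": {n: ms(v) for n, v in p2p.items()},
        "pt2crv": ms(crv),
        "measurements": meas,
    }
    if masks_hw is not None:
        report["dsc"] = ms(dices)
    return report
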