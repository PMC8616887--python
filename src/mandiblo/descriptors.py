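"""The four mandible descriptors.

1. Eleven linear distances and angles (18 scalars, bilateral codes carry
   separate left/right values) computed from the anatomical landmarks and
   the body/ramus margin semilandmarks.
2. Centroid size: the norm of the point-to-centroid distances.
3. Shape variations: the deviation of the aligned shape from the mean
   shape (length 2P = 192).
4. Shape parameters: the point-distribution-model projection (length k),
   optionally concatenated with centroid size.

Measurement geometry notes: the "mandibular angle" point is the gonion and
the "gnathion" is landmark IB; "vertical" distances are absolute
y-coordinate differences in the image frame (panoramic radiographs are
acquired upright). The mandibular angle a2 is measured between total
least-squares lines fitted through the lower body margin and posterior
ramus semilandmarks rather than between two-point chords.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import MandibleContour
from .morphometrics import ShapeModel, centroid_size_of

#: Canonical order of the 18 measurement scalars.
MEASUREMENT_ORDER = (
    "a1", "a2L", "a2R", "a3L", "a3R",
    "d1L", "d1R", "d2L", "d2R", "d3L", "d3R",
    "d4", "d5", "d6L", "d6R", "d7L", "d7R", "d8",
)

DESCRIPTOR_KINDS = (
    "measurements", "centroid_size", "shape_variations",
    "shape_params", "shape_params_plus_size",
)


@dataclass
class MeasurementSet:
    """The 18 scalars behind the 11 measurement codes.

    Angles in degrees; distances in mm when pixel spacing is known,
    otherwise px (see ``units``).
    """

    values: dict
    units: str = "px"

    def __getattr__(self, name):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)

    def vector(self) -> np.ndarray:
        return np.array([self.values[k] for k in MEASUREMENT_ORDER])


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= 1e-12 or nv <= 1e-12:
        raise ValueError("coincident points define no direction")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _tls_direction(pts: np.ndarray) -> np.ndarray:
    """Unit direction of the total-least-squares line through points."""
    d = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[0]


def _segment_points(c: MandibleContour, start: str, end: str) -> np.ndarray:
    """Landmarks + semilandmarks of one scheme segment, in order."""
    for s, e, sl in c.scheme.segment_slices():
        if s == start and e == end:
            idx = c.landmark_indices
            return np.vstack([
                c.points[idx[start]][None],
                c.points[sl],
                c.points[idx[end]][None],
            ])
    raise KeyError(f"no segment {start}-{end} in scheme")


def _margin_angle(c: MandibleContour, ramus_seg, body_seg, gonion, condyle, ib,
                  use_chords: bool) -> float:
    """a2: angle between the posterior ramus and lower body margin lines."""
    if use_chords:
        u = condyle - gonion
        v = ib - gonion
        return _angle_deg(u, v)
    ramus = _segment_points(c, *ramus_seg)
    body = _segment_points(c, *body_seg)
    u = _tls_direction(ramus)
    v = _tls_direction(body)
    # orient the fitted directions away from the gonion along each margin
    if np.dot(u, condyle - gonion) < 0:
        u = -u
    if np.dot(v, ib - gonion) < 0:
        v = -v
    return _angle_deg(u, v)


def measure(c: MandibleContour, use_chords: bool = False) -> MeasurementSet:
    """Compute the 11 linear distances and angles (19 scalars).

    Distances are reported in mm when the contour carries a pixel spacing,
    otherwise in px; angles are interior angles in degrees.
    """
    lm = {n: c.landmark(n) for n in c.landmark_indices}
    scale = 1.0 / c.px_per_mm if c.px_per_mm else 1.0
    units = "mm" if c.px_per_mm else "px"

    def dist(a, b):
        return float(np.linalg.norm(lm[a] - lm[b])) * scale

    def vdist(a, b):
        return float(abs(lm[a][1] - lm[b][1])) * scale

    v = {}
    v["a1"] = _angle_deg(lm["RG"] - lm["IB"], lm["LG"] - lm["IB"])
    v["a2R"] = _margin_angle(c, ("RC", "RG"), ("RG", "IB"),
                             lm["RG"], lm["RC"], lm["IB"], use_chords)
    v["a2L"] = _margin_angle(c, ("LG", "LC"), ("IB", "LG"),
                             lm["LG"], lm["LC"], lm["IB"], use_chords)
    v["a3R"] = _angle_deg(lm["RC"] - lm["RG"], lm["RCP"] - lm["RG"])
    v["a3L"] = _angle_deg(lm["LC"] - lm["LG"], lm["LCP"] - lm["LG"])
    v["d1R"] = dist("RG", "IB")
    v["d1L"] = dist("LG", "IB")
    v["d2R"] = dist("RG", "RC")
    v["d2L"] = dist("LG", "LC")
    v["d3R"] = dist("RG", "RCP")
    v["d3L"] = dist("LG", "LCP")
    v["d4"] = dist("RC", "LC")
    v["d5"] = dist("RG", "LG")
    v["d6R"] = vdist("RC", "RG")
    v["d6L"] = vdist("LC", "LG")
    v["d7R"] = vdist("RG", "IB")
    v["d7L"] = vdist("LG", "IB")
    v["d8"] = dist("SB", "IB")
    return MeasurementSet(values=v, units=units)


def centroid_size(c: MandibleContour) -> float:
    """sqrt(sum of squared point-to-centroid distances)."""
    pts = c.points if isinstance(c, MandibleContour) else np.asarray(c, float)
    return centroid_size_of(pts)


@dataclass
class DescriptorVector:
    kind: str
    values: np.ndarray
    contour_id: str | None = None


def build_descriptors(
    contours: list,
    kind: str,
    model: ShapeModel | None = None,
    ids: list | None = None,
) -> list:
    """Descriptor vectors of one kind for a list of contours.

    ``shape_variations``, ``shape_params`` and ``shape_params_plus_size``
    require a fitted :class:`ShapeModel`; centroid size is always computed
    on the unaligned contour so it keeps the original units.
    """
    if kind not in DESCRIPTOR_KINDS:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    if kind in ("shape_variations", "shape_params", "shape_params_plus_size") \
            and model is None:
        raise ValueError(f"descriptor kind {kind!r} requires a shape model")
    ids = ids if ids is not None else [str(i) for i in range(len(contours))]
    out = []
    for c, cid in zip(contours, ids):
        if kind == "measurements":
            vec = measure(c).vector()
        elif kind == "centroid_size":
            vec = np.array([centroid_size(c)])
        elif kind == "shape_variations":
            vec = model.align_to_frame(c) - model.mean
        elif kind == "shape_params":
            vec = model.project(c)
        else:  # shape_params_plus_size
            vec = np.concatenate(
                [model.project(c), [centroid_size(c)]]
            )
        out.append(DescriptorVector(kind=kind, values=vec, contour_id=cid))
    return out


def descriptor_matrix(descriptors: list) -> np.ndarray:
    return np.stack([d.values for d in descriptors])


def descriptor_columns(kind: str, k: int | None = None) -> list:
    """Column names for a descriptor table of the given kind."""
    if kind == "measurements":
        return list(MEASUREMENT_ORDER)
    if kind == "centroid_size":
        return ["csize"]
    if kind == "shape_variations":
        return [f"dx{i}" for i in range(192)]
    if kind == "shape_params":
        return [f"pc{i + 1}" for i in range(k)]
    if kind == "shape_params_plus_size":
        return [f"pc{i + 1}" for i in range(k)] + ["csize"]
    raise ValueError(f"unknown descriptor kind {kind!r}")
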