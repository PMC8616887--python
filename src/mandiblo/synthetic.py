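"""Seeded generator of mandible-like annotated contours and images.

Emulates the structure of a panoramic-radiograph mandible cohort so every
stage of the pipeline is testable without clinical data: a hand-designed
symmetric 96-point template is deformed by age-dependent growth (logistic
size increase saturating near adulthood), an age-dependent ramus-opening
mode (younger subjects have more open rami), an age-dependent
chin-pointiness mode, and a multiplicative sex size dimorphism; per-point
Gaussian annotation noise and irregular free-form semilandmark placement
emulate expert digitization; a soft-edged filled polygon over textured
background emulates the radiograph.

All randomness flows from explicitly passed ``numpy.random.Generator``
instances seeded from the cohort spec; there is no global state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .contour import (
    MandibleContour,
    RawAnnotation,
    AnatomicalLandmarks,
    contour_to_mask,
    resample_contour,
    write_annotation,
    write_contour,
    _arc_length_resample,
)
from .morphometrics import centroid_size_of
from .scheme import DEFAULT_SCHEME

FRAME_HW = (256, 512)
_MID_X = 256.0

# Right-side control points of the template outline (left side is the
# exact mirror about x = 256); layout follows the landmark geometry of a
# panoramic projection with the patient's right on the image's left.
_LANDMARKS_R = {
    "RC": (96.0, 56.0),
    "RG": (84.0, 186.0),
    "IB": (256.0, 226.0),
    "SB": (256.0, 128.0),
    "RCP": (140.0, 72.0),
}
_CONTROLS_R = {
    ("RC", "RG"): [(78.0, 120.0)],
    ("RG", "IB"): [(130.0, 216.0), (190.0, 226.0)],
    ("SB", "RCP"): [(200.0, 122.0), (160.0, 104.0)],
    ("RCP", "RC"): [(118.0, 84.0)],
}


def _mirror(p):
    return (2.0 * _MID_X - p[0], p[1])


def _spline_polyline(points, n=60):
    """Dense smooth polyline through control points (chord-length cubic)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 2:
        t = np.linspace(0, 1, n)
        return pts[0] + t[:, None] * (pts[1] - pts[0])
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(d)])
    cs = CubicSpline(t, pts, axis=0)
    return cs(np.linspace(0.0, t[-1], n))


def make_template() -> MandibleContour:
    """Fixed symmetric 96-point mandible-like contour in a 256x512 frame."""
    lms = dict(_LANDMARKS_R)
    lms["LC"] = _mirror(lms["RC"])
    lms["LG"] = _mirror(lms["RG"])
    lms["LCP"] = _mirror(lms["RCP"])

    polys = {}
    for (a, b), ctrl in _CONTROLS_R.items():
        polys[(a, b)] = _spline_polyline([lms[a], *ctrl, lms[b]])
    # mirror right-side segments onto the left, reversing traversal
    mirror_map = {
        ("IB", "LG"): ("RG", "IB"),
        ("LG", "LC"): ("RC", "RG"),
        ("LC", "LCP"): ("RCP", "RC"),
        ("LCP", "SB"): ("SB", "RCP"),
    }
    for left, right in mirror_map.items():
        m = polys[right].copy()[::-1]
        m[:, 0] = 2.0 * _MID_X - m[:, 0]
        polys[left] = m

    segments = {
        f"{a}-{b}": polys[(a, b)][1:-1] for a, b, _ in DEFAULT_SCHEME.segments
    }
    ann = RawAnnotation(
        landmarks=AnatomicalLandmarks({k: np.asarray(v) for k, v in lms.items()}),
        segments=segments,
        height=FRAME_HW[0],
        width=FRAME_HW[1],
    )
    return resample_contour(ann)


@dataclass
class CohortSpec:
    """Study-condition knobs of the synthetic cohort."""

    n: int = 100
    age_range: tuple = (5.0, 70.0)
    sex_ratio: float = 0.5           # proportion of males
    dimorphism: float = 1.06         # male centroid-size multiplier
    growth_floor: float = 0.55       # size fraction at birth-side asymptote
    growth_midpoint: float = 11.0    # years; steepest growth
    growth_scale: float = 3.5        # years; logistic width
    ramus_open_deg: float = 8.0      # extra ramus opening at youngest age
    chin_px: float = 6.0             # chin protrusion at oldest age
    ramus_jitter_deg: float = 1.5    # SD of individual ramus angle
    chin_jitter_px: float = 1.5      # SD of individual chin protrusion
    size_jitter: float = 0.04        # lognormal sigma of individual size
    noise_sd: float = 0.4            # px, per-point annotation noise
    semi_count_range: tuple = (12, 30)   # raw points per annotated segment
    image_hw: tuple = FRAME_HW
    render_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dimorphism <= 0:
            raise ValueError("dimorphism factor must be > 0")
        if self.noise_sd < 0 or self.render_noise < 0:
            raise ValueError("noise levels must be >= 0")


def growth_factor(spec: CohortSpec, age) -> float:
    """Monotone logistic size-vs-age curve, saturating near adulthood."""
    z = (np.asarray(age, dtype=float) - spec.growth_midpoint) / spec.growth_scale
    return spec.growth_floor + (1.0 - spec.growth_floor) / (1.0 + np.exp(-z))


def _age_norm(spec: CohortSpec, age: float) -> float:
    """Maturity in [0, 1] along the logistic growth curve.

    Shape remodeling (ramus closing, chin protrusion) follows the same
    saturating time course as size growth: most change is subadult.
    """
    lo, hi = spec.age_range
    g0, g1 = growth_factor(spec, lo), growth_factor(spec, hi)
    g = growth_factor(spec, np.clip(age, lo, hi))
    return float((g - g0) / max(g1 - g0, 1e-9))


def _ramus_rotation(points: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate each ramus about its gonion, weight ramping with height.

    Positive theta splays the rami outward (tops move laterally). The
    per-point weight is a smooth function of height above the gonion, so
    the deformation field is continuous along the contour.
    """
    idx = DEFAULT_SCHEME.landmark_indices
    out = points.copy()
    for side, sign in (("R", +1.0), ("L", -1.0)):
        g = points[idx[side + "G"]]
        c = points[idx[side + "C"]]
        span = max(g[1] - c[1], 1e-9)          # gonion below condyle
        w = np.clip((g[1] - points[:, 1]) / span, 0.0, 1.0)
        w = w * w * (3 - 2 * w)                 # smoothstep
        on_side = (points[:, 0] - _MID_X) * (g[0] - _MID_X) > 0
        w = np.where(on_side, w, 0.0)
        ang = sign * np.radians(theta_deg) * w
        ca, sa = np.cos(ang), np.sin(ang)
        rel = points - g
        out_x = g[0] + ca * rel[:, 0] - sa * rel[:, 1]
        out_y = g[1] + sa * rel[:, 0] + ca * rel[:, 1]
        sel = w > 0
        out[sel, 0] = out_x[sel]
        out[sel, 1] = out_y[sel]
    return out


def _chin_bump(points: np.ndarray, amount_px: float) -> np.ndarray:
    """Push points near the gnathion downward — a 'pointier' chin."""
    idx_ib = DEFAULT_SCHEME.landmark_indices["IB"]
    n = len(points)
    d = np.minimum(np.abs(np.arange(n) - idx_ib),
                   n - np.abs(np.arange(n) - idx_ib))
    bump = amount_px * np.exp(-(d.astype(float) ** 2) / (2.0 * 4.0**2))
    out = points.copy()
    out[:, 1] += bump
    return out


_TEMPLATE_CACHE = None


def _template_points() -> np.ndarray:
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        _TEMPLATE_CACHE = make_template().points
    return _TEMPLATE_CACHE.copy()


def deform_template(spec: CohortSpec, age: float, sex: str,
                    size_jitter_factor: float = 1.0,
                    ramus_jitter: float = 0.0,
                    chin_jitter: float = 0.0) -> MandibleContour:
    """Deterministic age/sex deformation of the template (no noise)."""
    t = _template_points()
    theta = spec.ramus_open_deg * (1.0 - _age_norm(spec, age)) + ramus_jitter
    pts = _ramus_rotation(t, theta)
    pts = _chin_bump(pts, spec.chin_px * _age_norm(spec, age) + chin_jitter)
    size = float(growth_factor(spec, age))
    if sex == "M":
        size *= spec.dimorphism
    size *= size_jitter_factor
    ctr = pts.mean(axis=0)
    pts = ctr + (pts - ctr) * size
    return MandibleContour(pts)


def sample_subject(spec: CohortSpec, age: float, sex: str,
                   rng: np.random.Generator) -> tuple:
    """One subject: free-form annotation, clean ground truth, metadata."""
    lo, hi = spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside spec range {spec.age_range}")
    jitter = float(np.exp(rng.normal(0.0, spec.size_jitter))) \
        if spec.size_jitter > 0 else 1.0
    rj = float(rng.normal(0.0, spec.ramus_jitter_deg)) \
        if spec.ramus_jitter_deg > 0 else 0.0
    cj = float(rng.normal(0.0, spec.chin_jitter_px)) \
        if spec.chin_jitter_px > 0 else 0.0
    clean = deform_template(spec, age, sex, size_jitter_factor=jitter,
                            ramus_jitter=rj, chin_jitter=cj)
    noisy = clean.points + rng.normal(0.0, spec.noise_sd, size=(96, 2)) \
        if spec.noise_sd > 0 else clean.points.copy()

    idx = DEFAULT_SCHEME.landmark_indices
    lms = {n: noisy[i].copy() for n, i in idx.items()}
    segments = {}
    for start, end, sl in DEFAULT_SCHEME.segment_slices():
        poly = np.vstack([noisy[idx[start]][None], noisy[sl],
                          noisy[idx[end]][None]])
        m = int(rng.integers(spec.semi_count_range[0],
                             spec.semi_count_range[1] + 1))
        # annotators spread clicks roughly evenly, with no exact protocol
        fracs = (np.arange(m) + rng.uniform(0.15, 0.85, size=m)) / m
        segments[f"{start}-{end}"] = _arc_length_resample(poly, fracs)
    ann = RawAnnotation(
        landmarks=AnatomicalLandmarks(lms),
        segments=segments,
        height=spec.image_hw[0],
        width=spec.image_hw[1],
    )
    meta = {
        "age": float(age),
        "sex": sex,
        "size_jitter": jitter,
        "centroid_size": centroid_size_of(clean.points),
    }
    return ann, clean, meta


def render_image(c: MandibleContour, hw: tuple = FRAME_HW,
                 noise: float = 0.05,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Radiograph-like grayscale rendering of the filled mandible.

    Soft-edged bright polygon over a darker textured background with
    additive Gaussian noise; intensities in [0, 1].
    """
    rng = rng or np.random.default_rng(0)
    mask = contour_to_mask(c, hw).astype(float)
    img = 0.20 + 0.55 * gaussian_filter(mask, 1.5)
    if noise > 0:
        # patient-specific trabecular/soft-tissue-like texture at two
        # spatial scales, normalized to unit std so `noise` sets its
        # visible amplitude directly
        coarse = gaussian_filter(rng.standard_normal(hw), 8.0)
        fine = gaussian_filter(rng.standard_normal(hw), 2.5)
        texture = coarse / coarse.std() + 0.6 * fine / fine.std()
        img = img + 1.5 * noise * texture
        img = img + 0.5 * noise * rng.standard_normal(hw)
    return np.clip(img, 0.0, 1.0)


@dataclass
class Cohort:
    spec: CohortSpec
    ids: list
    ages: np.ndarray
    sexes: list
    annotations: list
    contours: list                      # clean 96-point ground truth
    centroid_sizes: np.ndarray
    images: list | None = None
    meta: list = field(default_factory=list)


def make_cohort(spec: CohortSpec, render: bool = False) -> Cohort:
    """n seeded subjects; ages uniform over the range, sexes per ratio."""
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n)
    sexes = ["M" if rng.random() < spec.sex_ratio else "F"
             for _ in range(spec.n)]
    ids, anns, contours, sizes, metas, images = [], [], [], [], [], []
    for i, (age, sex) in enumerate(zip(ages, sexes)):
        ann, clean, meta = sample_subject(spec, age, sex, rng)
        ids.append(f"subj{i:04d}")
        anns.append(ann)
        contours.append(clean)
        sizes.append(meta["centroid_size"])
        metas.append(meta)
        if render:
            images.append(
                render_image(clean, spec.image_hw, spec.render_noise, rng)
            )
    return Cohort(
        spec=spec, ids=ids, ages=ages, sexes=sexes, annotations=anns,
        contours=contours, centroid_sizes=np.asarray(sizes),
        images=images if render else None, meta=metas,
    )


def write_cohort(cohort: Cohort, directory) -> None:
    """Dataset directory: PNG images, JSON annotations, CSV contours, table."""
    directory = Path(directory)
    for sub in ("images", "annotations", "contours"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(cohort.ids):
        write_annotation(cohort.annotations[i],
                         directory / "annotations" / f"{sid}.json")
        write_contour(cohort.contours[i],
                      directory / "contours" / f"{sid}.csv")
        if cohort.images is not None:
            arr = (cohort.images[i] * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(
                directory / "images" / f"{sid}.png"
            )
        rows.append({
            "id": sid,
            "age": f"{cohort.ages[i]:.3f}",
            "sex": cohort.sexes[i],
            "centroid_size": f"{cohort.centroid_sizes[i]:.6f}",
        })
    with open(directory / "cohort.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["id", "age", "sex", "centroid_size"])
        w.writeheader()
        w.writerows(rows)


def read_cohort_table(path) -> list:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
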