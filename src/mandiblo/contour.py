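"""Mandible contour containers, semilandmark resampling, rasterization, I/O.

The normalized contour holds exactly 96 ordered 2-D points: the eight
anatomical landmarks at fixed indices plus 88 semilandmarks equally spaced
by arc length within each segment of the annotated polyline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .scheme import DEFAULT_SCHEME, LANDMARK_ORDER, ContourScheme


class SchemaError(ValueError):
    """Malformed annotation or contour file."""


@dataclass
class AnatomicalLandmarks:
    """Eight named mandible landmarks in pixel coordinates (x, y)."""

    points: dict  # name -> (x, y)

    def __post_init__(self):
        missing = [n for n in LANDMARK_ORDER if n not in self.points]
        if missing:
            raise ValueError(f"missing anatomical landmark(s): {', '.join(missing)}")
        unknown = set(self.points) - set(LANDMARK_ORDER)
        if unknown:
            raise SchemaError(f"unknown landmark name(s): {sorted(unknown)}")
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (2,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name} is not a finite 2-D point")
            self.points[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def validate_bounds(self, height: int, width: int) -> None:
        for name, (x, y) in self.points.items():
            if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
                raise ValueError(
                    f"landmark {name} at ({x:.1f}, {y:.1f}) outside "
                    f"{height}x{width} image"
                )


@dataclass
class RawAnnotation:
    """Free-form expert annotation: landmarks plus per-segment polylines.

    Semilandmark polylines are ordered from the segment's start landmark
    toward its end landmark and may have any length >= 0; the landmarks
    themselves are not included in the polylines.
    """

    landmarks: AnatomicalLandmarks
    segments: dict  # "RC-RG" -> (m, 2) array
    height: int
    width: int
    px_per_mm: float | None = None
    image: str | None = None
    scheme: ContourScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self):
        keys = {f"{a}-{b}" for a, b, _ in self.scheme.segments}
        if set(self.segments) != keys:
            raise SchemaError(
                f"segment keys must be exactly {sorted(keys)}, "
                f"got {sorted(self.segments)}"
            )
        self.segments = {
            k: np.asarray(v, dtype=float).reshape(-1, 2)
            for k, v in self.segments.items()
        }


@dataclass
class MandibleContour:
    """96 ordered points tracing the closed mandible outline.

    ``points`` is a (96, 2) float array in the canonical traversal order
    RC -> RG -> IB -> LG -> LC -> LCP -> SB -> RCP -> (RC).
    """

    points: np.ndarray
    units: str = "px"
    px_per_mm: float | None = None
    scheme: ContourScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    flags: list = field(default_factory=list)  # indices of unreliable points

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (self.scheme.n_points, 2):
            raise ValueError(
                f"expected {self.scheme.n_points} contour points, "
                f"got {self.points.shape[0]}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("contour contains non-finite coordinates")

    @property
    def landmark_indices(self) -> dict:
        return self.scheme.landmark_indices

    def landmark(self, name: str) -> np.ndarray:
        return self.points[self.landmark_indices[name]]

    @property
    def landmarks(self) -> AnatomicalLandmarks:
        return AnatomicalLandmarks(
            {n: self.points[i].copy() for n, i in self.landmark_indices.items()}
        )

    def flatten(self) -> np.ndarray:
        """Length-2P vector (x0, y0, x1, y1, ...)."""
        return self.points.reshape(-1)

    @classmethod
    def from_flat(cls, vec: np.ndarray, **kw) -> "MandibleContour":
        return cls(np.asarray(vec, dtype=float).reshape(-1, 2), **kw)

    def transformed(self, fn) -> "MandibleContour":
        return MandibleContour(
            fn(self.points.copy()), units=self.units,
            px_per_mm=self.px_per_mm, scheme=self.scheme,
        )

    def labels(self) -> list:
        """Per-point label: landmark name or 'S' for semilandmarks."""
        inv = {i: n for n, i in self.landmark_indices.items()}
        return [inv.get(i, "S") for i in range(len(self.points))]


def _arc_length_resample(poly: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at given arc-length fractions of an open polyline."""
    deltas = np.diff(poly, axis=0)
    seg_len = np.hypot(deltas[:, 0], deltas[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length polyline")
    t = fractions * total
    x = np.interp(t, cum, poly[:, 0])
    y = np.interp(t, cum, poly[:, 1])
    return np.column_stack([x, y])


def resample_contour(
    ann: RawAnnotation, scheme: ContourScheme | None = None
) -> MandibleContour:
    """Normalize a free-form annotation to the fixed 96-point contour.

    Within each segment the polyline (start landmark, raw semilandmarks,
    end landmark) is arc-length parameterized and the scheme's semilandmark
    count is placed at equal arc-length fractions strictly between the
    endpoint landmarks, which pass through unchanged.
    """
    scheme = scheme or ann.scheme
    out = []
    for start, end, count in scheme.segments:
        p0 = ann.landmarks[start]
        p1 = ann.landmarks[end]
        raw = ann.segments[f"{start}-{end}"]
        poly = np.vstack([p0[None, :], raw, p1[None, :]])
        keep = np.concatenate(
            [[True], np.any(np.diff(poly, axis=0) != 0, axis=1)]
        )
        poly = poly[keep]
        if len(poly) < 2:
            raise ValueError(
                f"degenerate segment {start}-{end}: endpoints coincide and "
                "no distinct raw points were annotated"
            )
        fracs = np.arange(1, count + 1) / (count + 1)
        semis = _arc_length_resample(poly, fracs)
        out.append(p0[None, :])
        out.append(semis)
    return MandibleContour(
        np.vstack(out), px_per_mm=ann.px_per_mm, scheme=scheme
    )


def _even_odd_fill(pts: np.ndarray, height: int, width: int) -> np.ndarray:
    """Even-odd crossing-number rasterization (fallback for invalid polygons)."""
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    mask = np.zeros((height, width), dtype=bool)
    n = len(pts)
    for i in range(n):
        x0, y0 = pts[i]
        x1, y1 = pts[(i + 1) % n]
        cond = (y0 <= Y) != (y1 <= Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (Y - y0) * (x1 - x0) / (y1 - y0)
        mask ^= cond & (X < xint)
    return mask


def contour_to_mask(c: MandibleContour, hw: tuple) -> np.ndarray:
    """Rasterize the closed 96-point polygon to a binary (h, w) mask.

    A pixel is set when its center lies inside or on the polygon. A
    self-intersecting contour triggers a warning and an even-odd fill.
    """
    height, width = hw
    poly = shapely.Polygon(c.points)
    if not poly.is_valid:
        warnings.warn(
            "self-intersecting contour; applying even-odd fill rule",
            stacklevel=2,
        )
        return _even_odd_fill(c.points, height, width)
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    mask = shapely.intersects_xy(poly, X.ravel(), Y.ravel())
    return mask.reshape(height, width)


# ---------------------------------------------------------------- file I/O

def read_annotation(path) -> RawAnnotation:
    """Read an annotation JSON file (see the schema in the README)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    for key in ("height", "width", "landmarks", "segments"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required field '{key}'")
    try:
        lms = AnatomicalLandmarks(
            {str(k): v for k, v in doc["landmarks"].items()}
        )
    except (ValueError, TypeError) as e:
        raise SchemaError(f"{path}: {e}") from e
    try:
        return RawAnnotation(
            landmarks=lms,
            segments=doc["segments"],
            height=int(doc["height"]),
            width=int(doc["width"]),
            px_per_mm=doc.get("px_per_mm"),
            image=doc.get("image"),
        )
    except (ValueError, TypeError) as e:
        raise SchemaError(f"{path}: {e}") from e


def write_annotation(ann: RawAnnotation, path) -> None:
    doc = {
        "image": ann.image,
        "height": ann.height,
        "width": ann.width,
        "px_per_mm": ann.px_per_mm,
        "landmarks": {n: list(map(float, p)) for n, p in ann.landmarks.points.items()},
        "segments": {k: np.asarray(v).tolist() for k, v in ann.segments.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_contour(c: MandibleContour, path) -> None:
    """Write a contour CSV: index,label,x,y with full float precision."""
    lines = ["index,label,x,y"]
    for i, (label, (x, y)) in enumerate(zip(c.labels(), c.points)):
        lines.append(f"{i},{label},{float(x)!r},{float(y)!r}")
    if c.px_per_mm is not None:
        lines[0] += f"\n# px_per_mm={c.px_per_mm!r}"
    Path(path).write_text("\n".join(lines) + "\n")


def read_contour(path) -> MandibleContour:
    """Read a contour CSV written by :func:`write_contour`.

    Rows may appear in any order; they are sorted into canonical order by
    their index column.
    """
    path = Path(path)
    px_per_mm = None
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("index"):
            continue
        if line.startswith("#"):
            if "px_per_mm=" in line:
                px_per_mm = float(line.split("px_per_mm=")[1])
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise SchemaError(f"{path}:{ln}: expected 4 fields, got {len(parts)}")
        try:
            rows.append((int(parts[0]), parts[1], float(parts[2]), float(parts[3])))
        except ValueError as e:
            raise SchemaError(f"{path}:{ln}: {e}") from e
    n_expected = DEFAULT_SCHEME.n_points
    if len(rows) != n_expected:
        raise SchemaError(
            f"{path}: expected {n_expected} contour points, got {len(rows)}"
        )
    rows.sort(key=lambda r: r[0])
    if [r[0] for r in rows] != list(range(n_expected)):
        raise SchemaError(f"{path}: point indices must be 0..{n_expected - 1}")
    pts = np.array([(x, y) for _, _, x, y in rows], dtype=float)
    c = MandibleContour(pts, px_per_mm=px_per_mm)
    inv = {i: n for n, i in c.landmark_indices.items()}
    for i, label, _, _ in rows:
        expected = inv.get(i, "S")
        if label != expected:
            raise SchemaError(
                f"{path}: point {i} labeled '{label}', expected '{expected}'"
            )
    return c
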