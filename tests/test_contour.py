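"""Contour scheme, semilandmark resampling, rasterization, and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mandiblo.contour import (
    AnatomicalLandmarks,
    MandibleContour,
    RawAnnotation,
    SchemaError,
    contour_to_mask,
    read_annotation,
    read_contour,
    resample_contour,
    write_annotation,
    write_contour,
)
from mandiblo.scheme import DEFAULT_SCHEME, LANDMARK_ORDER


def test_scheme_structure():
    assert DEFAULT_SCHEME.n_points == 96
    assert DEFAULT_SCHEME.n_semilandmarks == 88
    counts = {(a, b): c for a, b, c in DEFAULT_SCHEME.segments}
    # per-side counts: condyle-gonion 8, gonion-IB 8, condyle-coronoid 10,
    # coronoid-SB 18
    assert counts[("RC", "RG")] == counts[("LG", "LC")] == 8
    assert counts[("RG", "IB")] == counts[("IB", "LG")] == 8
    assert counts[("LC", "LCP")] == counts[("RCP", "RC")] == 10
    assert counts[("LCP", "SB")] == counts[("SB", "RCP")] == 18
    # closed loop: landmark indices are segment endpoints
    idx = DEFAULT_SCHEME.landmark_indices
    assert idx["RC"] == 0
    assert sorted(idx) == sorted(LANDMARK_ORDER)


def _square_annotation(side=10.0, n_raw=3):
    """Degenerate 'mandible' on a square path, for geometry checks."""
    rng = np.random.default_rng(0)
    corners = {
        "RC": (0.0, 0.0), "RG": (0.0, side), "IB": (side / 2, side),
        "LG": (side, side), "LC": (side, 0.0), "LCP": (side * 0.8, 0.0),
        "SB": (side / 2, 0.0), "RCP": (side * 0.2, 0.0),
    }
    lms = AnatomicalLandmarks({k: np.array(v) for k, v in corners.items()})
    segments = {}
    for a, b, _ in DEFAULT_SCHEME.segments:
        p0, p1 = np.array(corners[a]), np.array(corners[b])
        t = np.sort(rng.uniform(0.1, 0.9, size=n_raw))
        segments[f"{a}-{b}"] = p0 + t[:, None] * (p1 - p0)
    return RawAnnotation(landmarks=lms, segments=segments, height=20, width=20)


def test_resample_point_count_and_landmarks():
    ann = _square_annotation()
    c = resample_contour(ann)
    assert c.points.shape == (96, 2)
    assert sum(1 for l in c.labels() if l == "S") == 88
    for name in LANDMARK_ORDER:
        np.testing.assert_allclose(c.landmark(name), ann.landmarks[name])


def test_resample_equal_spacing_on_straight_segment():
    """On a straight segment of length L, semis sit at L*i/(c+1)."""
    ann = _square_annotation(side=10.0)
    c = resample_contour(ann)
    for start, end, sl in DEFAULT_SCHEME.segment_slices():
        p0, p1 = ann.landmarks[start], ann.landmarks[end]
        count = sl.stop - sl.start
        expect = p0 + (np.arange(1, count + 1) / (count + 1))[:, None] * (p1 - p0)
        np.testing.assert_allclose(c.points[sl], expect, atol=1e-9)


def test_resample_idempotent():
    ann = _square_annotation()
    c1 = resample_contour(ann)
    idx = DEFAULT_SCHEME.landmark_indices
    segs = {
        f"{a}-{b}": c1.points[sl]
        for (a, b, _), (_, _, sl) in zip(
            DEFAULT_SCHEME.segments, DEFAULT_SCHEME.segment_slices()
        )
    }
    ann2 = RawAnnotation(
        landmarks=AnatomicalLandmarks({n: c1.points[i] for n, i in idx.items()}),
        segments=segs, height=20, width=20,
    )
    c2 = resample_contour(ann2)
    np.testing.assert_allclose(c2.points, c1.points, atol=1e-9)


def test_resample_invariant_under_densification():
    """Inserting collinear midpoints must not move the output."""
    ann = _square_annotation()
    c1 = resample_contour(ann)
    dense_segs = {}
    for a, b, _ in DEFAULT_SCHEME.segments:
        poly = np.vstack([
            ann.landmarks[a][None], ann.segments[f"{a}-{b}"],
            ann.landmarks[b][None],
        ])
        mids = (poly[:-1] + poly[1:]) / 2
        dense = np.empty((len(poly) + len(mids), 2))
        dense[0::2] = poly
        dense[1::2] = mids
        dense_segs[f"{a}-{b}"] = dense[1:-1]
    ann2 = RawAnnotation(
        landmarks=ann.landmarks, segments=dense_segs, height=20, width=20
    )
    c2 = resample_contour(ann2)
    np.testing.assert_allclose(c2.points, c1.points, atol=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_resample_always_96_points(seed):
    """Property: output has 96 points for any raw semilandmark counts."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(10, 90, size=(8, 2))
    lms = AnatomicalLandmarks(dict(zip(LANDMARK_ORDER, pts)))
    segments = {}
    for a, b, _ in DEFAULT_SCHEME.segments:
        m = int(rng.integers(0, 30))
        t = np.sort(rng.uniform(0.05, 0.95, size=m))
        p0, p1 = lms[a], lms[b]
        jitter = rng.normal(0, 1.0, size=(m, 2))
        segments[f"{a}-{b}"] = p0 + t[:, None] * (p1 - p0) + jitter
    ann = RawAnnotation(landmarks=lms, segments=segments, height=100, width=100)
    c = resample_contour(ann)
    assert c.points.shape == (96, 2)
    # equal arc-length gaps within each segment along the raw polyline
    for start, end, sl in DEFAULT_SCHEME.segment_slices():
        seg = np.vstack([
            lms[start][None], c.points[sl], lms[end][None],
        ])
        gaps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        # chord gaps of an equal-arclength sampling of a polyline are not
        # exactly equal; check total consistency instead on straight parts
        assert np.all(gaps > 0)


def test_resample_errors():
    ann = _square_annotation()
    with pytest.raises(ValueError, match="RC"):
        AnatomicalLandmarks({k: v for k, v in ann.landmarks.points.items()
                             if k != "RC"})
    bad = _square_annotation()
    bad.landmarks.points["RC"] = bad.landmarks.points["RG"].copy()
    bad.segments["RC-RG"] = np.empty((0, 2))
    with pytest.raises(ValueError, match="degenerate segment"):
        resample_contour(bad)


def test_mask_rectangle_area(template):
    """Axis-aligned rectangle contour -> exactly w*h pixels inside."""
    pts = template.points.copy()
    # build a rectangle traversal preserving the 96-point structure
    x0, x1, y0, y1 = 3.0, 12.0, 2.0, 9.0
    t = np.linspace(0, 4, 97)[:-1]
    rect = np.empty((96, 2))
    for i, u in enumerate(t):
        if u < 1:
            rect[i] = (x0 + u * (x1 - x0), y0)
        elif u < 2:
            rect[i] = (x1, y0 + (u - 1) * (y1 - y0))
        elif u < 3:
            rect[i] = (x1 - (u - 2) * (x1 - x0), y1)
        else:
            rect[i] = (x0, y1 - (u - 3) * (y1 - y0))
    mask = contour_to_mask(MandibleContour(rect), (16, 16))
    assert mask.sum() == 10 * 8  # inclusive pixel-center count


def test_mask_determinism_and_shift(template):
    m1 = contour_to_mask(template, (256, 512))
    m2 = contour_to_mask(template, (256, 512))
    np.testing.assert_array_equal(m1, m2)
    shifted = template.transformed(lambda p: p + np.array([1.0, 0.0]))
    m3 = contour_to_mask(shifted, (256, 512))
    np.testing.assert_array_equal(m3[:, 1:], m1[:, :-1])


def test_mask_matches_brute_force_point_in_polygon():
    """Small-grid oracle: even-odd ray casting per pixel center."""
    rng = np.random.default_rng(3)
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=96))
    r = 5 + rng.uniform(0, 2, size=96)
    pts = np.column_stack([8 + r * np.cos(ang), 8 + r * np.sin(ang)])
    c = MandibleContour(pts)
    mask = contour_to_mask(c, (16, 16))

    def inside(px, py):
        cnt = False
        for i in range(96):
            x0, y0 = pts[i]
            x1, y1 = pts[(i + 1) % 96]
            if (y0 <= py) != (y1 <= py):
                xi = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
                if px < xi:
                    cnt = not cnt
        return cnt

    oracle = np.array([[inside(x, y) for x in range(16)] for y in range(16)])
    # boundary pixels may differ between inclusive and strict rules
    disagreements = (mask != oracle).sum()
    assert disagreements <= 4


def test_self_intersecting_polygon_warns():
    pts = np.zeros((96, 2))
    t = np.linspace(0, 2 * np.pi, 96, endpoint=False)
    # figure-eight
    pts[:, 0] = 8 + 6 * np.sin(2 * t)
    pts[:, 1] = 8 + 6 * np.sin(t)
    with pytest.warns(UserWarning, match="self-intersecting"):
        contour_to_mask(MandibleContour(pts), (16, 16))


def test_contour_roundtrip(tmp_path, template):
    path = tmp_path / "c.csv"
    c = MandibleContour(template.points, px_per_mm=11.11)
    write_contour(c, path)
    c2 = read_contour(path)
    np.testing.assert_array_equal(c2.points, c.points)  # bitwise
    assert c2.px_per_mm == 11.11


def test_contour_read_reorders_rows(tmp_path, template):
    path = tmp_path / "c.csv"
    write_contour(template, path)
    lines = path.read_text().splitlines()
    header, rows = lines[0], lines[1:]
    rows = rows[::-1]
    path.write_text("\n".join([header] + rows) + "\n")
    c2 = read_contour(path)
    np.testing.assert_array_equal(c2.points, template.points)


def test_contour_read_rejects_wrong_count(tmp_path, template):
    path = tmp_path / "c.csv"
    write_contour(template, path)
    lines = path.read_text().splitlines()
    path.write_text("\n".join(lines[:-1]) + "\n")
    with pytest.raises(SchemaError, match="96"):
        read_contour(path)


def test_annotation_roundtrip(tmp_path):
    ann = _square_annotation()
    path = tmp_path / "a.json"
    write_annotation(ann, path)
    ann2 = read_annotation(path)
    for n in LANDMARK_ORDER:
        np.testing.assert_array_equal(ann2.landmarks[n], ann.landmarks[n])
    for k in ann.segments:
        np.testing.assert_array_equal(ann2.segments[k], ann.segments[k])


def test_annotation_unknown_landmark_rejected(tmp_path):
    ann = _square_annotation()
    path = tmp_path / "a.json"
    write_annotation(ann, path)
    doc = path.read_text().replace('"RC"', '"XX"', 1)
    path.write_text(doc)
    with pytest.raises(SchemaError):
        read_annotation(path)
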