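"""Generalized Procrustes analysis and the point distribution model.

Shapes are aligned by full similarity transforms (translation, unit
centroid-size scaling, rotation without reflection), making the aligned
coordinates and everything derived from them size-free; size is carried
separately as centroid size. The point distribution model decomposes the
deviations from the mean shape, ΔX = X − X̄, with a singular value
decomposition ΔX = U Σ Vᵀ; the squared singular values give each mode's
proportion of total shape variance, and the smallest k whose cumulative
proportion reaches the threshold l is retained.  Shapes project to the
k-dimensional parameter space as b = (x − X̄) V_k and reconstruct as
X̄ + b V_kᵀ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contour import MandibleContour


def centroid_size_of(points: np.ndarray) -> float:
    """Euclidean norm of the point-to-centroid distances of a configuration."""
    pts = np.asarray(points, dtype=float)
    d = pts - pts.mean(axis=0)
    return float(np.sqrt((d * d).sum()))


def _center_and_scale(points: np.ndarray) -> tuple:
    c = points.mean(axis=0)
    centered = points - c
    size = np.sqrt((centered * centered).sum())
    if size <= 1e-12:
        raise ValueError("degenerate shape: zero centroid size")
    return centered / size, float(size)


def _rotate_onto(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation (det +1; reflections excluded)."""
    m = shape.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, d]) @ vt
    return shape @ rot


@dataclass
class AlignedShapeSet:
    """GPA-aligned cohort: rows of X are flattened unit-size shapes."""

    X: np.ndarray                  # (n, 2P)
    mean: np.ndarray               # (2P,)
    centroid_sizes: np.ndarray     # (n,) original sizes in input units
    n_points: int = 96

    @property
    def deviations(self) -> np.ndarray:
        """ΔX = X − X̄, the shape-variation descriptor rows."""
        return self.X - self.mean

    def shape(self, i: int) -> np.ndarray:
        return self.X[i].reshape(-1, 2)


def gpa_align(
    shapes: list, tol: float = 1e-10, max_iter: int = 100
) -> AlignedShapeSet:
    """Iterative generalized Procrustes alignment of 96-point contours.

    Each shape is centered, scaled to unit centroid size, and repeatedly
    rotated onto the running mean until the mean changes by less than
    ``tol``. Deterministic given input order.
    """
    if len(shapes) < 2:
        raise ValueError("GPA needs at least 2 shapes")
    pts_list, sizes = [], []
    for i, s in enumerate(shapes):
        pts = s.points if isinstance(s, MandibleContour) else np.asarray(s, float)
        try:
            unit, size = _center_and_scale(pts)
        except ValueError as e:
            raise ValueError(f"shape {i}: {e}") from e
        pts_list.append(unit)
        sizes.append(size)
    arr = np.stack(pts_list)                      # (n, P, 2)
    # The Procrustes rotation is invariant to the reference's scale, so the
    # plain sample mean serves as reference; the stored X̄ is then exactly
    # the mean of the aligned rows and ΔX has zero column means.
    mean = arr[0].copy()
    for _ in range(max_iter):
        arr = np.stack([_rotate_onto(a, mean) for a in arr])
        new_mean = arr.mean(axis=0)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    arr = np.stack([_rotate_onto(a, mean) for a in arr])
    mean = arr.mean(axis=0)
    n = len(arr)
    return AlignedShapeSet(
        X=arr.reshape(n, -1),
        mean=mean.reshape(-1),
        centroid_sizes=np.asarray(sizes),
        n_points=arr.shape[1],
    )


@dataclass
class ShapeModel:
    """Point distribution model fitted to aligned shape deviations."""

    mean: np.ndarray              # X̄, (2P,)
    modes: np.ndarray             # V, (2P, r), orthonormal columns
    singular_values: np.ndarray   # Σ diagonal, nonincreasing
    variance_threshold: float     # l
    n_samples: int
    n_points: int = 96

    @property
    def proportions(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum()

    @property
    def k(self) -> int:
        if self.variance_threshold >= 1.0:
            return len(self.singular_values)     # full numerical rank
        cum = np.cumsum(self.proportions)
        return int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)

    # ------------------------------------------------------------- frame
    def align_to_frame(self, shape) -> np.ndarray:
        """Center, scale to unit size, and rotate a shape onto X̄."""
        pts = shape.points if isinstance(shape, MandibleContour) else np.asarray(shape, float)
        if pts.size == self.mean.size:
            pts = pts.reshape(-1, 2)
        if pts.shape[0] != self.n_points:
            raise ValueError(
                f"expected {self.n_points} points, got {pts.shape[0]}"
            )
        unit, _ = _center_and_scale(pts)
        return _rotate_onto(unit, self.mean.reshape(-1, 2)).reshape(-1)

    def project(self, shape, k: int | None = None, prealigned: bool = False) -> np.ndarray:
        """Shape parameters b = (x − X̄) V_k."""
        k = self.k if k is None else k
        if k > self.modes.shape[1]:
            raise ValueError(f"k={k} exceeds available modes ({self.modes.shape[1]})")
        x = (
            np.asarray(shape, float).reshape(-1)
            if prealigned
            else self.align_to_frame(shape)
        )
        return (x - self.mean) @ self.modes[:, :k]

    def reconstruct(self, params, k: int | None = None) -> MandibleContour:
        """Shape X̄ + b V_kᵀ from the first k parameters."""
        params = np.atleast_1d(np.asarray(params, dtype=float))
        k = len(params) if k is None else k
        if k > self.modes.shape[1]:
            raise ValueError(f"k={k} exceeds available modes ({self.modes.shape[1]})")
        if len(params) < k:
            raise ValueError(f"need {k} parameters, got {len(params)}")
        vec = self.mean + params[:k] @ self.modes[:, :k].T
        return MandibleContour(vec.reshape(-1, 2))

    # ------------------------------------------------------------ storage
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "variance_threshold": self.variance_threshold,
            "k": self.k,
            "n_samples": self.n_samples,
            "n_points": self.n_points,
            "proportions": self.proportions.tolist(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(directory / "mean.csv", self.mean, delimiter=",")
        np.savetxt(directory / "modes.csv", self.modes, delimiter=",")
        np.savetxt(directory / "singular_values.csv", self.singular_values,
                   delimiter=",")

    @classmethod
    def load(cls, directory) -> "ShapeModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        return cls(
            mean=np.loadtxt(directory / "mean.csv", delimiter=","),
            modes=np.loadtxt(directory / "modes.csv", delimiter=",", ndmin=2),
            singular_values=np.atleast_1d(
                np.loadtxt(directory / "singular_values.csv", delimiter=",")
            ),
            variance_threshold=meta["variance_threshold"],
            n_samples=meta["n_samples"],
            n_points=meta["n_points"],
        )


def fit_pdm(aligned: AlignedShapeSet, l: float = 0.95) -> ShapeModel:
    """Fit the point distribution model by SVD of ΔX.

    Modes with singular values below 1e-9 of the largest are dropped as
    numerical rank deficiency. Mode signs are fixed so the largest-
    magnitude component of each mode is positive, making fits stable
    across SVD implementations.
    """
    if not 0 < l <= 1:
        raise ValueError("variance threshold l must be in (0, 1]")
    dx = aligned.deviations
    u, s, vt = np.linalg.svd(dx, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("no shape variation in the aligned set")
    keep = s > 1e-9 * s[0]
    s, vt = s[keep], vt[keep]
    flips = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    vt = vt * flips[:, None]
    return ShapeModel(
        mean=aligned.mean.copy(),
        modes=vt.T,
        singular_values=s,
        variance_threshold=l,
        n_samples=dx.shape[0],
        n_points=aligned.n_points,
    )


def group_mean_reconstruction(
    model: ShapeModel,
    projections: np.ndarray,
    labels,
    sizes=None,
    with_size: bool = False,
) -> dict:
    """Per-group mean shape from the first variation mode.

    For each group the mean of the first-mode scores is reconstructed with
    k = 1; with ``with_size`` the shape (centered at the origin) is scaled
    by the group's mean centroid size, restoring the size component.
    """
    projections = np.asarray(projections, dtype=float)
    labels = np.asarray(labels)
    if with_size:
        if sizes is None:
            raise ValueError("with_size=True requires centroid sizes")
        sizes = np.asarray(sizes, dtype=float)
    out = {}
    for g in np.unique(labels):
        sel = labels == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        b1 = float(projections[sel, 0].mean())
        shape = model.reconstruct(np.array([b1]), k=1)
        if with_size:
            shape = MandibleContour(shape.points * sizes[sel].mean())
        out[g] = shape
    return out


def procrustes_distance(a, b) -> float:
    """Root-sum-square distance between two unit-aligned configurations."""
    pa = a.points if isinstance(a, MandibleContour) else np.asarray(a, float)
    pb = b.points if isinstance(b, MandibleContour) else np.asarray(b, float)
    ua, _ = _center_and_scale(pa.reshape(-1, 2))
    ub, _ = _center_and_scale(pb.reshape(-1, 2))
    ua = _rotate_onto(ua, ub)
    return float(np.linalg.norm(ua - ub))
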