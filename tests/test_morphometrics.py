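"""GPA alignment and the point distribution model."""

import numpy as np
import pytest

from mandiblo.contour import MandibleContour
from mandiblo.morphometrics import (
    centroid_size_of,
    fit_pdm,
    gpa_align,
    group_mean_reconstruction,
    procrustes_distance,
)


def _random_shapes(rng, n, scale=1.0):
    base = rng.normal(0, 10, size=(96, 2))
    return [
        MandibleContour(base + scale * rng.normal(0, 1, size=(96, 2)))
        for _ in range(n)
    ]


def _similarity(rng, pts):
    th = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    s = rng.uniform(0.3, 3.0)
    t = rng.uniform(-50, 50, size=2)
    return s * pts @ rot.T + t


class TestGPA:
    def test_similarity_invariance_of_pair(self, rng):
        shape = _random_shapes(rng, 1)[0]
        moved = MandibleContour(_similarity(rng, shape.points))
        aligned = gpa_align([shape, moved])
        d = np.linalg.norm(aligned.X[0] - aligned.X[1])
        assert d < 1e-8

    def test_unit_size_and_centering(self, rng):
        aligned = gpa_align(_random_shapes(rng, 5))
        for i in range(5):
            s = aligned.shape(i)
            assert np.abs(s.mean(axis=0)).max() < 1e-8
            assert abs(np.linalg.norm(s - s.mean(axis=0)) - 1.0) < 1e-8

    def test_mean_is_sample_mean(self, rng):
        aligned = gpa_align(_random_shapes(rng, 3))
        np.testing.assert_allclose(
            aligned.X.mean(axis=0), aligned.mean, atol=1e-12
        )
        assert np.abs(aligned.deviations.mean(axis=0)).max() < 1e-8
        assert np.abs(aligned.deviations.sum(axis=0)).max() < 1e-6

    def test_idempotence(self, rng):
        aligned = gpa_align(_random_shapes(rng, 6))
        again = gpa_align(
            [MandibleContour(aligned.shape(i)) for i in range(6)]
        )
        for i in range(6):
            assert procrustes_distance(aligned.shape(i), again.shape(i)) < 1e-8

    def test_invariance_under_cohort_transforms(self, rng, clean_cohort):
        """Random similarity transform of every input barely moves the
        aligned shapes (up to the global rotation GPA leaves free)."""
        shapes = clean_cohort.contours[:12]
        a1 = gpa_align(shapes)
        moved = [
            MandibleContour(_similarity(rng, s.points)) for s in shapes
        ]
        a2 = gpa_align(moved)
        for i in range(len(shapes)):
            assert procrustes_distance(a1.shape(i), a2.shape(i)) < 1e-6

    def test_degenerate_shape_rejected(self):
        ok = MandibleContour(np.random.default_rng(0).normal(size=(96, 2)))
        flat = MandibleContour(np.tile([5.0, 5.0], (96, 1)))
        with pytest.raises(ValueError, match="shape 1"):
            gpa_align([ok, flat])


class TestPDM:
    def test_rank_one_data(self, rng):
        base = rng.normal(0, 10, size=(96, 2))
        v = rng.normal(0, 1, size=(96, 2))
        v -= v.mean(axis=0)
        shapes = [MandibleContour(base + a * v) for a in rng.normal(0, 0.1, 20)]
        aligned = gpa_align(shapes)
        model = fit_pdm(aligned, l=0.5)
        assert model.proportions[0] > 0.999
        assert model.k == 1
        model_full = fit_pdm(aligned, l=1.0)
        assert model_full.k == len(model_full.singular_values)

    def test_orthonormal_modes(self, rng):
        aligned = gpa_align(_random_shapes(rng, 15))
        model = fit_pdm(aligned)
        g = model.modes.T @ model.modes
        np.testing.assert_allclose(g, np.eye(g.shape[0]), atol=1e-8)
        assert abs(model.proportions.sum() - 1.0) < 1e-8
        assert np.all(np.diff(model.singular_values) <= 1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Oracle: eigendecomposition of the deviation covariance."""
        aligned = gpa_align(_random_shapes(rng, 10))
        model = fit_pdm(aligned, l=1.0)
        dx = aligned.deviations
        evals, evecs = np.linalg.eigh(dx.T @ dx)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        r = len(model.singular_values)
        np.testing.assert_allclose(
            model.singular_values**2, evals[:r], atol=1e-8 * evals[0]
        )
        props_oracle = evals[:r] / evals[evals > 1e-12 * evals[0]].sum()
        np.testing.assert_allclose(model.proportions, props_oracle, atol=1e-8)
        for j in range(r):
            dot = abs(model.modes[:, j] @ evecs[:, j])
            assert dot > 1 - 1e-8  # equal up to sign

    def test_variance_proportion_recovery_three_modes(self, rng):
        """n=500 synthetic set from 3 orthogonal modes, variances 4:1:0.25."""
        q, _ = np.linalg.qr(rng.normal(size=(192, 3)))
        sds = np.array([2.0, 1.0, 0.5])
        base = np.zeros(192)
        coefs = rng.normal(0, 1, size=(500, 3)) * sds
        X = base + coefs @ q.T
        dx = X - X.mean(axis=0)

        class A:  # minimal aligned-set stand-in
            deviations = dx
            mean = X.mean(axis=0)
            n_points = 96
        model = fit_pdm(A(), l=0.95)
        expect = sds**2 / (sds**2).sum()   # (0.762, 0.190, 0.048)
        np.testing.assert_allclose(expect, [0.7619, 0.19048, 0.047619],
                                   atol=1e-4)
        np.testing.assert_allclose(model.proportions[:3], expect, atol=0.02)

    def test_invalid_threshold(self, rng):
        aligned = gpa_align(_random_shapes(rng, 4))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                fit_pdm(aligned, l=bad)


class TestProjection:
    def test_mean_projects_to_zero(self, rng):
        aligned = gpa_align(_random_shapes(rng, 8))
        model = fit_pdm(aligned)
        b = model.project(aligned.mean, prealigned=True)
        np.testing.assert_allclose(b, 0.0, atol=1e-10)

    def test_project_reconstruct_roundtrip(self, rng):
        aligned = gpa_align(_random_shapes(rng, 8))
        model = fit_pdm(aligned, l=1.0)
        k = model.k
        b = rng.normal(0, 0.05, size=k)
        rec = model.reconstruct(b, k=k)
        b2 = model.project(rec.flatten(), k=k, prealigned=True)
        np.testing.assert_allclose(b2, b, atol=1e-8)

    def test_full_rank_reconstruction_of_training_shapes(self, rng):
        aligned = gpa_align(_random_shapes(rng, 8))
        model = fit_pdm(aligned, l=1.0)
        kfull = len(model.singular_values)
        for i in range(8):
            b = model.project(aligned.X[i], k=kfull, prealigned=True)
            rec = model.reconstruct(b, k=kfull)
            assert np.abs(rec.flatten() - aligned.X[i]).max() < 1e-8

    def test_projection_variance_matches_singular_values(self, rng):
        aligned = gpa_align(_random_shapes(rng, 20))
        model = fit_pdm(aligned, l=1.0)
        B = aligned.deviations @ model.modes
        np.testing.assert_allclose(
            (B**2).sum(axis=0), model.singular_values**2, rtol=1e-8
        )

    def test_reconstruction_error_monotone_in_k(self, rng):
        aligned = gpa_align(_random_shapes(rng, 12))
        model = fit_pdm(aligned, l=1.0)
        kmax = len(model.singular_values)
        x = aligned.X[0]
        b = model.project(x, k=kmax, prealigned=True)
        errs = [
            np.linalg.norm(model.reconstruct(b[:k], k=k).flatten() - x)
            for k in range(1, kmax + 1)
        ]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))

    def test_eckart_young_tail_sum(self, rng):
        """Total k-mode reconstruction error = discarded variance tail."""
        aligned = gpa_align(_random_shapes(rng, 10))
        model = fit_pdm(aligned, l=1.0)
        for k in (1, 3):
            B = aligned.deviations @ model.modes[:, :k]
            recon = B @ model.modes[:, :k].T
            sq_err = ((aligned.deviations - recon) ** 2).sum()
            tail = (model.singular_values[k:] ** 2).sum()
            np.testing.assert_allclose(sq_err, tail, rtol=1e-8)

    def test_k_exceeding_modes_rejected(self, rng):
        aligned = gpa_align(_random_shapes(rng, 5))
        model = fit_pdm(aligned, l=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            model.reconstruct(np.zeros(500), k=500)


class TestGroupMeanReconstruction:
    def test_single_group_centered_scores_give_mean(self, rng):
        aligned = gpa_align(_random_shapes(rng, 10))
        model = fit_pdm(aligned)
        B = aligned.deviations @ model.modes[:, : model.k]
        out = group_mean_reconstruction(
            model, B, labels=np.zeros(10, dtype=int)
        )
        # scores of training deviations are centered, so the grand mean
        # reconstruction is the mean shape itself
        np.testing.assert_allclose(
            out[0].flatten(), model.mean, atol=1e-8
        )

    def test_pure_size_effect_scales_output(self, rng):
        aligned = gpa_align(_random_shapes(rng, 10))
        model = fit_pdm(aligned)
        B = np.zeros((10, model.k))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        sizes = np.array([1.0] * 5 + [2.0] * 5)
        out = group_mean_reconstruction(
            model, B, labels, sizes=sizes, with_size=True
        )
        np.testing.assert_allclose(out["b"].points, 2.0 * out["a"].points,
                                   atol=1e-12)

    def test_group_shift_along_mode1(self, rng):
        aligned = gpa_align(_random_shapes(rng, 10))
        model = fit_pdm(aligned)
        B = np.zeros((10, max(model.k, 1)))
        B[5:, 0] += 0.3
        labels = np.array(["A"] * 5 + ["B"] * 5)
        out = group_mean_reconstruction(model, B, labels)
        diff = out["B"].flatten() - out["A"].flatten()
        v1 = model.modes[:, 0]
        cos = abs(diff @ v1) / np.linalg.norm(diff)
        assert cos > 1 - 1e-6

    def test_empty_group_rejected(self, rng):
        aligned = gpa_align(_random_shapes(rng, 4))
        model = fit_pdm(aligned)
        with pytest.raises(ValueError, match="sizes"):
            group_mean_reconstruction(
                model, np.zeros((4, 1)), np.zeros(4), with_size=True
            )


def test_centroid_size_unit_square():
    pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
    assert abs(centroid_size_of(pts) - np.sqrt(2)) < 1e-12
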