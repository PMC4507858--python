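"""Outline resampling and the two Fourier decompositions."""

import numpy as np
import pytest

from morphovar import (
    Outline,
    RadialDescriptor,
    efa_orient,
    elliptic_fourier,
    inverse_radial_fourier,
    radial_fourier,
    resample_equal_arclength,
)
from morphovar._warnings import (
    DegenerateReconstructionWarning,
    OrientationUndefinedWarning,
)


def circle(radius=1.0, n=128, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return Outline(radius * np.column_stack([np.cos(t), np.sin(t)]))


def ellipse(a=2.0, b=1.0, n=256, rot=0.0, start=0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    return Outline(np.roll(pts @ R.T, start, axis=0))


def blob(n=64, a0=3.0, seed=5, h_min=2, h_max=7, amp=0.03):
    """Smooth radial blob with harmonic content in [h_min, h_max] only,
    sampled at equal angles (centroid exactly at the origin for h_min>=2)."""
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n) / n
    r = np.ones(n)
    for h in range(h_min, h_max + 1):
        r += amp * rng.uniform(-1, 1) * np.cos(h * theta)
        r += amp * rng.uniform(-1, 1) * np.sin(h * theta)
    r *= a0
    return Outline(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


class TestOutlineValidation:
    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            Outline([[0, 0], [1, 1]])

    def test_rejects_duplicate_consecutive_points(self):
        with pytest.raises(ValueError, match="duplicate"):
            Outline([[0, 0], [0, 0], [1, 1], [0, 1]])

    def test_rejects_closing_duplicate(self):
        with pytest.raises(ValueError, match="duplicate"):
            Outline([[0, 0], [1, 0], [1, 1], [0, 0]])

    def test_counterclockwise_flips_clockwise_ring(self):
        cw = Outline([[0, 0], [0, 1], [1, 1], [1, 0]])
        ccw = cw.counterclockwise()
        assert ccw.signed_area() > 0
        assert np.allclose(ccw.points[0], [0, 0])  # same starting point


class TestResample:
    def test_square_to_eight_points_hits_corners_and_midpoints(self):
        square = Outline([[0, 0], [1, 0], [1, 1], [0, 1]])
        out = resample_equal_arclength(square, 8)
        expected = np.array(
            [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1], [0, 0.5]]
        )
        np.testing.assert_allclose(out.points, expected, atol=1e-12)

    def test_circle_keeps_every_second_point(self):
        c = circle(n=128)
        out = resample_equal_arclength(c, 64)
        np.testing.assert_allclose(out.points, c.points[::2], atol=1e-9)

    def test_irregular_polygon_gaps_equal(self, rng):
        theta = np.sort(rng.uniform(0, 2 * np.pi, 10))
        r = rng.uniform(1, 3, 10)
        poly = Outline(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        out = resample_equal_arclength(poly, 64)
        per = poly.perimeter()
        # arc-length gaps measured directly on the source polygon: locate
        # each output point on its segment and re-accumulate arc positions
        from morphovar.outline import _cumulative_arclength

        s = _cumulative_arclength(poly.points)
        closed_in = np.vstack([poly.points, poly.points[0]])
        pos = []
        for pt in out.points:
            # locate pt on its segment
            best = None
            for i in range(len(s) - 1):
                seg = closed_in[i + 1] - closed_in[i]
                L = np.linalg.norm(seg)
                tau = np.clip((pt - closed_in[i]) @ seg / L**2, 0, 1)
                dist = np.linalg.norm(closed_in[i] + tau * seg - pt)
                if best is None or dist < best[0]:
                    best = (dist, s[i] + tau * L)
            pos.append(best[1])
        arc_gaps = np.diff(np.array(pos + [pos[0] + per]))
        np.testing.assert_allclose(arc_gaps, per / 64, rtol=1e-9)

    def test_degenerate_n_points(self):
        with pytest.raises(ValueError):
            resample_equal_arclength(circle(), 2)


class TestEllipticFourier:
    def test_circle_first_harmonic_is_radius(self):
        R = 2.0
        desc = elliptic_fourier(circle(R, 256), 5)
        np.testing.assert_allclose(
            [desc.a[0], desc.b[0], desc.c[0], desc.d[0]], [R, 0, 0, R], atol=1e-3 * R
        )
        assert np.max(np.abs(np.concatenate([desc.a[1:], desc.b[1:], desc.c[1:], desc.d[1:]]))) < 1e-4 * R

    def test_translation_changes_only_dc_terms(self):
        o = ellipse()
        shifted = Outline(o.points + np.array([3.5, -1.25]))
        d0, d1 = elliptic_fourier(o, 7), elliptic_fourier(shifted, 7)
        for name in "abcd":
            np.testing.assert_allclose(getattr(d0, name), getattr(d1, name), atol=1e-12)
        assert np.isclose(d1.A0 - d0.A0, 3.5, atol=1e-12)
        assert np.isclose(d1.C0 - d0.C0, -1.25, atol=1e-12)

    def test_matches_dense_integration_oracle_on_ellipse(self):
        """Coefficients of the arc-length expansion agree with a brute-force
        trapezoidal Fourier integral over a densely resampled contour."""
        o = ellipse(2.0, 1.0, 256)
        desc = elliptic_fourier(o, 3)
        dense = resample_equal_arclength(o, 20000).points
        n = dense.shape[0]
        t = np.arange(n) / n
        for h in range(1, 4):
            a_or = 2 * np.mean(dense[:, 0] * np.cos(2 * np.pi * h * t))
            c_or = 2 * np.mean(dense[:, 1] * np.cos(2 * np.pi * h * t))
            b_or = 2 * np.mean(dense[:, 0] * np.sin(2 * np.pi * h * t))
            d_or = 2 * np.mean(dense[:, 1] * np.sin(2 * np.pi * h * t))
            np.testing.assert_allclose(
                [desc.a[h - 1], desc.b[h - 1], desc.c[h - 1], desc.d[h - 1]],
                [a_or, b_or, c_or, d_or],
                atol=2e-4,
            )

    def test_inverse_expansion_reproduces_vertices(self):
        o = blob(n=64)
        desc = elliptic_fourier(o, 30)
        from morphovar.outline import _cumulative_arclength

        s = _cumulative_arclength(o.points)
        rec = desc.evaluate(s[:-1] / s[-1])
        assert np.abs(rec - o.points).max() < 0.02  # discretization error


class TestOrient:
    def test_rotated_ellipse_aligned_to_x_axis(self):
        o = ellipse(2.0, 1.0, 256, rot=np.deg2rad(30), start=71)
        oriented = efa_orient(o)
        # major axis along x: extremal x-extent ~ 2, y-extent ~ 1
        assert abs(np.abs(oriented.points[:, 0]).max() - 2.0) < 0.01
        assert abs(np.abs(oriented.points[:, 1]).max() - 1.0) < 0.01
        # starting point at the +x intersection, within one arc step
        step = o.perimeter() / o.n_points
        assert np.linalg.norm(oriented.points[0] - [2, 0]) < step

    def test_idempotent_on_aligned_ellipse(self):
        o = efa_orient(ellipse(2.0, 1.0, 256))
        o2 = efa_orient(o)
        assert np.abs(o.points - o2.points).max() < 1e-6

    def test_circle_warns_and_returns_input(self):
        c = circle(n=64)
        with pytest.warns(OrientationUndefinedWarning):
            out = efa_orient(c)
        np.testing.assert_allclose(out.points, c.points)

    def test_start_index_invariance(self):
        o = ellipse(2.0, 1.0, 256, rot=0.7)
        a = efa_orient(o)
        b = efa_orient(Outline(np.roll(o.points, 100, axis=0)))
        step = o.perimeter() / o.n_points
        assert np.linalg.norm(a.points[0] - b.points[0]) < step


class TestRadialFourier:
    def test_circle_gives_pure_size(self):
        desc = radial_fourier(circle(3.0, 64))
        assert np.isclose(desc.a0, 3.0, atol=1e-9)
        assert np.abs(desc.fcs).max() < 1e-12

    @pytest.mark.parametrize("k", [0.1, 1.0, 17.3])
    def test_scale_invariance(self, k):
        o = blob()
        d1 = radial_fourier(o)
        d2 = radial_fourier(Outline(k * o.points))
        assert np.isclose(d2.a0, k * d1.a0, rtol=1e-12)
        np.testing.assert_allclose(d2.fcs, d1.fcs, atol=1e-12)

    def test_matches_brute_force_dft_oracle(self):
        o = blob(seed=9)
        desc = radial_fourier(o)
        pts = o.points
        ctr = pts.mean(axis=0)
        r = np.hypot(*(pts - ctr).T)
        n = len(r)
        for h in range(1, 8):
            A = 2.0 / n * sum(r[j] * np.cos(2 * np.pi * h * j / n) for j in range(n))
            B = 2.0 / n * sum(r[j] * np.sin(2 * np.pi * h * j / n) for j in range(n))
            assert np.isclose(desc.cosine[h - 1], A / r.mean(), atol=1e-12)
            assert np.isclose(desc.sine[h - 1], B / r.mean(), atol=1e-12)

    def test_ellipse_harmonic_two_dominates(self):
        o = resample_equal_arclength(ellipse(2.0, 1.0, 512), 64)
        desc = radial_fourier(o)
        mags = np.hypot(desc.cosine, desc.sine)
        assert np.argmax(mags) == 1  # harmonic 2

    def test_parseval_bound(self, rng):
        for seed in range(5):
            o = blob(seed=seed, amp=0.05)
            desc = radial_fourier(o)
            pts = o.points
            r = np.hypot(*(pts - pts.mean(axis=0)).T)
            raw_sq = np.sum((desc.fcs * desc.a0) ** 2)
            assert raw_sq <= 2.0 / len(r) * np.sum(r**2) + 1e-12


class TestInverseRadial:
    def test_zero_descriptor_gives_circle(self):
        o = inverse_radial_fourier(RadialDescriptor(1.0, np.zeros(14)), 64)
        r = np.hypot(*o.points.T)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_roundtrip_recovers_radius_series(self):
        o = blob(seed=2)
        desc = radial_fourier(o)
        rec = inverse_radial_fourier(desc, 64)
        r_orig = np.hypot(*(o.points - o.points.mean(axis=0)).T)
        r_rec = np.hypot(*rec.points.T)
        np.testing.assert_allclose(r_rec, r_orig, atol=1e-9)

    def test_linearity_in_a0(self):
        desc = radial_fourier(blob(seed=3))
        doubled = RadialDescriptor(2 * desc.a0, desc.fcs, desc.n_harmonics)
        o1 = inverse_radial_fourier(desc, 64)
        o2 = inverse_radial_fourier(doubled, 64)
        np.testing.assert_allclose(o2.points, 2 * o1.points, atol=1e-12)

    def test_degenerate_radius_warns(self):
        fcs = np.zeros(14)
        fcs[0] = 1.5  # radius dips below zero
        with pytest.warns(DegenerateReconstructionWarning):
            inverse_radial_fourier(RadialDescriptor(1.0, fcs), 64)
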