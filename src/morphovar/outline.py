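"""Closed-outline Fourier descriptors.

A tooth (or any closed 2-D shape) is digitized as an ordered ring of points.
Two complementary Fourier decompositions are provided:

* **Elliptic Fourier analysis (EFA)** expands x(t) and y(t) against the
  cumulative arc length t (Kuhl & Giardina form).  Its first harmonic is the
  best-fitting ellipse, used here only to normalize the outline: rotate the
  major axis onto +x and move the starting point to the intersection of the
  outline with that axis.
* **Radial Fourier analysis** expands the centroid-to-contour distance
  r(t) sampled at N equally spaced arc positions.  The zero harmonic a0
  (mean radius) is proportional to size; dividing the remaining
  coefficients by a0 leaves pure shape variables.  With H = 7 harmonics the
  outline is summarised by 14 dimensionless coefficients, the shape
  variables used throughout the rest of the package.

All functions treat the outline as a closed polygon (the last point
connects back to the first) and force counterclockwise orientation before
analysis so the sine coefficients have a consistent sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._warnings import DegenerateReconstructionWarning, OrientationUndefinedWarning

#: Minor/major axis ratio above which the first-harmonic ellipse is treated
#: as a circle and orientation is left undefined.
NEAR_CIRCULAR_AXIS_RATIO = 0.99


@dataclass(frozen=True)
class Outline:
    """An ordered closed ring of 2-D points (closed polygon)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise ValueError("an outline needs at least 3 points")
        closed = np.vstack([pts, pts[0]])
        steps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive duplicate points (including the closing edge)")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[0]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def counterclockwise(self) -> "Outline":
        """Return the outline traversed counterclockwise (reverse if needed)."""
        if self.signed_area() < 0:
            rev = self.points[::-1]
            rev = np.roll(rev, 1, axis=0)  # keep the same starting point
            return Outline(rev)
        return self


@dataclass(frozen=True)
class EllipticDescriptor:
    """Elliptic Fourier coefficients: per harmonic (a, b) for x and (c, d)
    for y; (A0, C0) locate the outline centroid."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    A0: float
    C0: float

    def __post_init__(self) -> None:
        for name in "abcd":
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (len(self.a) == len(self.b) == len(self.c) == len(self.d) >= 1):
            raise ValueError("coefficient arrays must share a common length >= 1")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Reconstruct (x, y) at normalized parameter t in [0, 1)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        h = np.arange(1, self.n_harmonics + 1)
        ang = 2.0 * np.pi * np.outer(t, h)
        x = self.A0 + np.cos(ang) @ self.a + np.sin(ang) @ self.b
        y = self.C0 + np.cos(ang) @ self.c + np.sin(ang) @ self.d
        return np.column_stack([x, y])


@dataclass(frozen=True)
class RadialDescriptor:
    """Size (a0) plus 2H size-standardized radial Fourier coefficients.

    ``fcs`` holds A1..AH (cosine) then B1..BH (sine), each divided by a0,
    hence invariant under uniform scaling of the outline.
    """

    a0: float
    fcs: np.ndarray
    n_harmonics: int = 7

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        fcs = np.asarray(self.fcs, dtype=float)
        if fcs.shape != (2 * self.n_harmonics,):
            raise ValueError("fcs must have length 2 * n_harmonics")
        object.__setattr__(self, "fcs", fcs)

    @property
    def cosine(self) -> np.ndarray:
        return self.fcs[: self.n_harmonics]

    @property
    def sine(self) -> np.ndarray:
        return self.fcs[self.n_harmonics :]


# ---------------------------------------------------------------------------
# resampling

def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    closed = np.vstack([points, points[0]])
    steps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def resample_equal_arclength(outline: Outline, n_points: int) -> Outline:
    """Resample the closed contour at ``n_points`` equal arc-length steps.

    Linear interpolation between vertices; the first output point is the
    input's first point.
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    pts = outline.points
    s = _cumulative_arclength(pts)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    closed = np.vstack([pts, pts[0]])
    targets = np.arange(n_points) * total / n_points
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    return Outline(out)


def _point_at_arclength(outline: Outline, s0: float) -> np.ndarray:
    pts = outline.points
    s = _cumulative_arclength(pts)
    closed = np.vstack([pts, pts[0]])
    s0 = s0 % s[-1]
    return np.array([np.interp(s0, s, closed[:, 0]), np.interp(s0, s, closed[:, 1])])


def _resample_from(outline: Outline, s0: float, n_points: int) -> Outline:
    """Equal-arc resampling starting at arc position s0 (fractional allowed)."""
    pts = outline.points
    s = _cumulative_arclength(pts)
    total = s[-1]
    closed = np.vstack([pts, pts[0]])
    targets = (s0 + np.arange(n_points) * total / n_points) % total
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return Outline(np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# elliptic Fourier analysis

def elliptic_fourier(outline: Outline, n_harmonics: int) -> EllipticDescriptor:
    """Closed-contour elliptic Fourier expansion (Kuhl & Giardina form).

    x(t) and y(t) are expanded against the cumulative chord length t of the
    closed polygon; coefficients are exact for the polygonal contour, so the
    inverse expansion converges to the vertices as harmonics accumulate.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = outline.points
    closed = np.vstack([pts, pts[0]])
    dxy = np.diff(closed, axis=0)
    dt = np.linalg.norm(dxy, axis=1)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    h = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    phi = 2.0 * np.pi * t / T  # (n+1,)
    dcos = np.cos(h * phi[1:]) - np.cos(h * phi[:-1])  # (H, n)
    dsin = np.sin(h * phi[1:]) - np.sin(h * phi[:-1])
    const = T / (2.0 * np.pi**2 * h.ravel() ** 2)
    vx = dxy[:, 0] / dt
    vy = dxy[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    d = const * (dsin @ vy)
    # DC terms: piecewise-linear average of x(t), y(t) over one period.
    xi = np.concatenate([[0.0], np.cumsum(dxy[:-1, 0])]) - vx * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(dxy[:-1, 1])]) - vy * t[:-1]
    A0 = pts[0, 0] + float(np.sum(vx / 2 * (t[1:] ** 2 - t[:-1] ** 2) + xi * dt) / T)
    C0 = pts[0, 1] + float(np.sum(vy / 2 * (t[1:] ** 2 - t[:-1] ** 2) + delta * dt) / T)
    return EllipticDescriptor(a, b, c, d, A0, C0)


def _first_harmonic_axes(desc: EllipticDescriptor) -> tuple[float, float, float]:
    """Return (tau, major, minor): parameter shift of the semi-major point
    and the semi-axis lengths of the first-harmonic ellipse."""
    a1, b1, c1, d1 = desc.a[0], desc.b[0], desc.c[0], desc.d[0]
    tau = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    ct, st = np.cos(tau), np.sin(tau)
    major_vec = np.array([a1 * ct + b1 * st, c1 * ct + d1 * st])
    minor_vec = np.array([-a1 * st + b1 * ct, -c1 * st + d1 * ct])
    major, minor = np.linalg.norm(major_vec), np.linalg.norm(minor_vec)
    if major < minor:  # tau pointed at the minor axis; shift a quarter period
        tau += np.pi / 2.0
        major, minor = minor, major
    return float(tau % (2 * np.pi)), float(major), float(minor)


def efa_orient(outline: Outline, n_harmonics: int = 7) -> Outline:
    """Normalize rotation and starting point via the first-harmonic ellipse.

    The outline is rotated so the major axis of its best-fitting ellipse
    lies along +x and resampled so the starting point sits at the outline's
    intersection with that axis, on the end of major elongation (the
    candidate whose EFA-reconstructed point has the larger rotated x; ties
    go to the intersection nearer the input starting point).  Near-circular
    outlines (axis ratio above ``NEAR_CIRCULAR_AXIS_RATIO``) are returned
    unchanged with :class:`OrientationUndefinedWarning`.
    """
    outline = outline.counterclockwise()
    desc = elliptic_fourier(outline, n_harmonics)
    tau, major, minor = _first_harmonic_axes(desc)
    if minor / major > NEAR_CIRCULAR_AXIS_RATIO:
        warnings.warn(
            "outline is near-circular; orientation undefined, returning input",
            OrientationUndefinedWarning,
        )
        return outline
    total = outline.perimeter()
    candidates = []
    for k in (0, 1):
        tau_c = (tau + k * np.pi) % (2 * np.pi)
        p = desc.evaluate(tau_c / (2 * np.pi))[0] - np.array([desc.A0, desc.C0])
        psi = np.arctan2(
            desc.c[0] * np.cos(tau_c) + desc.d[0] * np.sin(tau_c),
            desc.a[0] * np.cos(tau_c) + desc.b[0] * np.sin(tau_c),
        )
        x_rec = p[0] * np.cos(-psi) - p[1] * np.sin(-psi)
        s0 = tau_c / (2 * np.pi) * total
        dist_to_start = min(s0, total - s0)
        candidates.append((x_rec, -dist_to_start, psi, s0))
    x0, d0 = candidates[0][0], candidates[0][1]
    x1, d1 = candidates[1][0], candidates[1][1]
    pick = candidates[0] if (x0, d0) >= (x1, d1) else candidates[1]
    _, _, psi, s0 = pick
    # already oriented: skip the resampling pass so repeated orientation is
    # a strict no-op instead of accumulating interpolation error
    if abs(psi) < 1e-9 and min(s0, total - s0) < 1e-9 * total:
        return outline
    rot = np.array([[np.cos(-psi), -np.sin(-psi)], [np.sin(-psi), np.cos(-psi)]])
    rotated = Outline(outline.points @ rot.T)
    return _resample_from(rotated, s0, outline.n_points)


# ---------------------------------------------------------------------------
# radial Fourier analysis

def radial_fourier(outline64: Outline, n_harmonics: int = 7) -> RadialDescriptor:
    """Radial Fourier decomposition of an equally arc-length-spaced outline.

    With N points and radii r_j from the centroid (mean of the points):
    a0 = mean(r); A_h = (2/N) sum_j r_j cos(2 pi h j / N) and B_h likewise
    with sine.  Returned coefficients are divided by a0, making them pure
    shape variables.
    """
    pts = outline64.counterclockwise().points
    n = pts.shape[0]
    if n < 2 * n_harmonics + 1:
        raise ValueError("need at least 2 * n_harmonics + 1 points")
    centroid = pts.mean(axis=0)
    r = np.linalg.norm(pts - centroid, axis=1)
    a0 = float(r.mean())
    if a0 <= 0:
        raise ValueError("degenerate outline: all points at the centroid")
    j = np.arange(n)
    h = np.arange(1, n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * h * j / n
    A = (2.0 / n) * (np.cos(ang) @ r)
    B = (2.0 / n) * (np.sin(ang) @ r)
    return RadialDescriptor(a0, np.concatenate([A, B]) / a0, n_harmonics)


def inverse_radial_fourier(desc: RadialDescriptor, n_points: int) -> Outline:
    """Rebuild an outline from a radial descriptor.

    Radii are evaluated at ``n_points`` positions and plotted against equal
    angular steps around the centroid — a display-oriented approximation of
    the arc-length parameter, adequate for mean-shape figures.  A zero-fcs
    descriptor yields a circle of radius a0.
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    j = np.arange(n_points)
    h = np.arange(1, desc.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * h * j / n_points
    r = desc.a0 * (1.0 + desc.cosine @ np.cos(ang) + desc.sine @ np.sin(ang))
    if np.any(r <= 0):
        warnings.warn(
            "reconstructed radius non-positive; descriptor outside validity",
            DegenerateReconstructionWarning,
        )
    theta = 2.0 * np.pi * j / n_points
    return Outline(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def digitize(
    outline: Outline, n_points: int = 64, n_harmonics: int = 7
) -> RadialDescriptor:
    """Full descriptor pipeline: resample to ``n_points`` equal arc steps,
    normalize rotation/starting point on the first-harmonic ellipse, then
    take the size-standardized radial Fourier coefficients."""
    resampled = resample_equal_arclength(outline.counterclockwise(), n_points)
    oriented = efa_orient(resampled, n_harmonics)
    return radial_fourier(oriented, n_harmonics)


def read_outline(path) -> Outline:
    """Read a plain-text outline file: one "x y" pair per line."""
    pts = np.loadtxt(path, dtype=float)
    return Outline(np.atleast_2d(pts))


def write_outline(outline: Outline, path) -> None:
    np.savetxt(path, outline.points, fmt="%.10g")
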