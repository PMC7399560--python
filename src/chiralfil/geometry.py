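"""Shared differential-geometry helpers for discrete space curves.

Rotation-minimizing (twist-free) frames via the double-reflection method,
Rodrigues rotations, arc-length splines, and the discrete local polar
writhe integrand used both by the twist/writhe measurements and by the
generator's linking bookkeeping.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def unitize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / n


def rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate vector(s) v about a unit axis by angle (radians)."""
    c, s = np.cos(angle), np.sin(angle)
    return (v * c + np.cross(axis, v) * s
            + axis * np.dot(v, axis) * (1.0 - c))


def arclength_spline(points: np.ndarray):
    """Cubic spline of a polyline parameterized by cumulative chord length.

    Returns (spline, s_nodes); spline maps arclength -> position.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return CubicSpline(s, points, axis=0), s


def resample_uniform(points: np.ndarray, n_out: int,
                     total_length: float | None = None):
    """Resample a polyline at n_out points uniformly spaced in arclength.

    Points are placed at s_j = j * ds with ds = L / n_out (the transform
    convention l_c = N * ds), so the last sample sits at L - ds.
    """
    cs, s = arclength_spline(points)
    L = total_length if total_length is not None else s[-1]
    ds = L / n_out
    s_new = np.arange(n_out) * ds
    s_new = np.clip(s_new, 0.0, s[-1])
    return cs(s_new), ds


def rotation_minimizing_frame(points: np.ndarray,
                              normal0: np.ndarray | None = None):
    """Twist-free orthonormal frames (t, f1, f2) along a polyline.

    Uses the double-reflection method (Wang et al. 2008), which transports
    the normal with no spurious twist to fourth order in the step.  The
    frames satisfy f1 x f2 = t.

    Returns arrays t, f1, f2 of shape (n, 3).
    """
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    # node tangents from central differences
    t = np.zeros((n, 3))
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    t[1:-1] = points[2:] - points[:-2]
    t = unitize(t)
    f1 = np.zeros((n, 3))
    if normal0 is None:
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, t[0])) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        normal0 = trial
    r0 = normal0 - np.dot(normal0, t[0]) * t[0]
    nr = np.linalg.norm(r0)
    if nr < 1e-12:
        raise ValueError("initial normal parallel to initial tangent")
    f1[0] = r0 / nr
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        rL = f1[i] - (2.0 / c1) * np.dot(v1, f1[i]) * v1
        tL = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-28:
            f1[i + 1] = rL
        else:
            f1[i + 1] = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        f1[i + 1] -= np.dot(f1[i + 1], t[i + 1]) * t[i + 1]
        f1[i + 1] /= np.linalg.norm(f1[i + 1])
    f2 = np.cross(t, f1)
    return t, f1, f2


def polar_writhe_points(points: np.ndarray, u: np.ndarray) -> float:
    """Local polar writhe density (1/nm) of a discrete curve about axis u.

    Evaluates (1 / 2 pi l_c) * int ds  u.(t x t') / (1 + u.t) on cubic
    spline interpolants with composite Simpson quadrature on a 4x
    oversampled grid.  Raises ValueError if the curve has a turning point
    in u (the local decomposition then no longer applies).
    """
    cs, s = arclength_spline(points)
    L = s[-1]
    m = 4 * (points.shape[0] - 1)
    if m % 2:
        m += 1
    sg = np.linspace(0.0, L, m + 1)
    d1 = cs(sg, 1)
    d2 = cs(sg, 2)
    speed = np.linalg.norm(d1, axis=1)
    t = d1 / speed[:, None]
    ru_rate = t @ u
    if np.any(ru_rate <= 0.0):
        bad = sg[np.argmin(ru_rate)]
        raise ValueError(
            f"turning point in the u direction near s = {bad:.2f} nm; "
            "local polar writhe undefined")
    # dt/ds = (I - t t^T) r'' / |r'|
    dt = (d2 - (np.sum(d2 * t, axis=1)[:, None]) * t) / speed[:, None]
    integrand = (np.cross(t, dt) @ u) / (1.0 + ru_rate)
    from scipy.integrate import simpson
    total = simpson(integrand, x=sg)
    return total / (2.0 * np.pi * L)


def gyration_axes(points: np.ndarray):
    """Principal axes of the gyration tensor of a point set.

    Returns (eigenvalues descending, eigenvectors as columns), with the
    centroid removed.  Sign conventions are applied by the caller.
    """
    x = points - points.mean(axis=0)
    g = x.T @ x / x.shape[0]
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]
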