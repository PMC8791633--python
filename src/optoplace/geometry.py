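"""Arena geometry, ellipse fitting and trajectory linearization.

The recording arena is an O-shaped linear maze: an elliptical path of fixed
width inside a rectangular bounding box.  Positions on the closed track are
reduced to one dimension by projecting each x-y sample onto the ellipse that
best approximates the trajectory and taking the arc length of the projection
along the ellipse — a circular coordinate s in [0, perimeter).

Ellipse fitting uses the numerically stable direct least-squares conic fit of
Halir & Flusser, which is constrained to return an ellipse (never a parabola
or hyperbola) for any non-degenerate input.  Projection is radial
(center-anchored): the sample is mapped to the ellipse point on the ray from
the ellipse center through the sample.  For points near the track of a
low-eccentricity ellipse the difference from the true closest-point
projection is far below the spatial bin width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class FitError(ValueError):
    """Ellipse fitting failed (degenerate or underdetermined input)."""


class ProjectionError(ValueError):
    """A point could not be projected onto the ellipse."""


# number of parameter samples used for the cumulative arc-length table;
# gives ~1e-8 relative perimeter accuracy for track-like eccentricities
_ARC_GRID = 8192


@dataclass
class EllipseModel:
    """Axis lengths a >= b, center in cm, rotation of the major axis in rad."""

    center: tuple
    a: float
    b: float
    rotation: float = 0.0
    _arc_table: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.center = (float(self.center[0]), float(self.center[1]))
        self.a, self.b = float(self.a), float(self.b)
        self.rotation = float(self.rotation)
        if not (self.a >= self.b > 0):
            raise FitError(f"ellipse axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")

    def _table(self):
        if self._arc_table is None:
            t = np.linspace(0.0, 2 * np.pi, _ARC_GRID + 1)
            integrand = np.hypot(self.a * np.sin(t), self.b * np.cos(t))
            # cumulative trapezoid arc length over the parameter grid
            ds = 0.5 * (integrand[1:] + integrand[:-1]) * np.diff(t)
            s = np.concatenate([[0.0], np.cumsum(ds)])
            self._arc_table = (t, s)
        return self._arc_table

    @property
    def perimeter(self) -> float:
        return float(self._table()[1][-1])

    def arc_length(self, t: np.ndarray) -> np.ndarray:
        """Arc length from parameter 0 to parameter t in [0, 2*pi)."""
        grid_t, grid_s = self._table()
        return np.interp(np.mod(t, 2 * np.pi), grid_t, grid_s)

    def point(self, t: np.ndarray) -> np.ndarray:
        """Cartesian point(s) at parametric angle t."""
        t = np.asarray(t, dtype=float)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        out = np.stack([c * x - s * y, s * x + c * y], axis=-1)
        return out + np.asarray(self.center)

    def tangent(self, t: np.ndarray) -> np.ndarray:
        """Unit tangent vector(s) in the direction of increasing t."""
        t = np.asarray(t, dtype=float)
        dx = -self.a * np.sin(t)
        dy = self.b * np.cos(t)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        v = np.stack([c * dx - s * dy, s * dx + c * dy], axis=-1)
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    def normal(self, t: np.ndarray) -> np.ndarray:
        """Outward unit normal vector(s)."""
        t = np.asarray(t, dtype=float)
        nx = np.cos(t) / self.a
        ny = np.sin(t) / self.b
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        v = np.stack([c * nx - s * ny, s * nx + c * ny], axis=-1)
        return v / np.linalg.norm(v, axis=-1, keepdims=True)


@dataclass
class MazeGeometry:
    """O-shaped linear maze: elliptical midline track of a given path width
    inside a rectangular bounding box (origin at lower-left corner)."""

    bounding_box_cm: tuple = (70.0, 50.0)
    path_width_cm: float = 9.0
    center_cm: tuple = (35.0, 25.0)
    semi_axes_cm: tuple = (30.5, 20.5)

    def __post_init__(self):
        self.bounding_box_cm = (float(self.bounding_box_cm[0]), float(self.bounding_box_cm[1]))
        self.center_cm = (float(self.center_cm[0]), float(self.center_cm[1]))
        self.semi_axes_cm = (float(self.semi_axes_cm[0]), float(self.semi_axes_cm[1]))
        a, b = self.semi_axes_cm
        half = self.path_width_cm / 2.0
        w, h = self.bounding_box_cm
        cx, cy = self.center_cm
        if (cx - a - half < -1e-9 or cx + a + half > w + 1e-9
                or cy - b - half < -1e-9 or cy + b + half > h + 1e-9):
            raise ValueError("midline ellipse plus half path width must fit in the bounding box")

    @property
    def midline(self) -> EllipseModel:
        a, b = self.semi_axes_cm
        return EllipseModel(center=self.center_cm, a=max(a, b), b=min(a, b))

    def to_dict(self) -> dict:
        return {
            "bounding_box_cm": list(self.bounding_box_cm),
            "path_width_cm": self.path_width_cm,
            "center_cm": list(self.center_cm),
            "semi_axes_cm": list(self.semi_axes_cm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeGeometry":
        return cls(
            bounding_box_cm=tuple(d["bounding_box_cm"]),
            path_width_cm=float(d["path_width_cm"]),
            center_cm=tuple(d["center_cm"]),
            semi_axes_cm=tuple(d["semi_axes_cm"]),
        )


def fit_ellipse(positions: np.ndarray) -> EllipseModel:
    """Direct least-squares ellipse fit (Halir & Flusser 1998).

    Parameters
    ----------
    positions : (n, 2) array of x-y samples, n >= 6, not collinear.

    Returns
    -------
    EllipseModel with a >= b and rotation in [0, pi).
    """
    xy = np.asarray(positions, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise FitError("positions must be an (n, 2) array")
    xy = xy[~np.isnan(xy).any(axis=1)]
    if xy.shape[0] < 6:
        raise FitError("ellipse fit requires at least 6 points")
    mean = xy.mean(axis=0)
    x = xy[:, 0] - mean[0]
    y = xy[:, 1] - mean[1]

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate input (collinear or coincident points)") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C), C the ellipse-constraint matrix
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where(np.isreal(eigval) & (cond > 0))[0]
    if good.size == 0:
        raise FitError("no elliptical solution (degenerate input)")
    a1 = np.real(eigvec[:, good[0]])
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in centered frame
    A, B, C, D, E, F = coeffs

    den = B * B - 4 * A * C
    if den >= 0:
        raise FitError("fitted conic is not an ellipse")
    x0 = (2 * C * D - B * E) / den
    y0 = (2 * A * E - B * D) / den
    # constant term at the center
    Fc = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(Q)
    axes2 = -Fc / lam
    if np.any(axes2 <= 0):
        raise FitError("fitted conic is not an ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]  # major first
    a_len, b_len = axes[order]
    major_vec = vec[:, order[0]]
    rotation = float(np.mod(np.arctan2(major_vec[1], major_vec[0]), np.pi))
    return EllipseModel(
        center=(x0 + mean[0], y0 + mean[1]), a=float(a_len), b=float(b_len),
        rotation=rotation,
    )


def linearize(positions: np.ndarray, ellipse: EllipseModel) -> np.ndarray:
    """Map x-y positions to circular arc-length coordinates on the ellipse.

    Each point is projected radially (from the ellipse center) onto the
    ellipse and mapped to the arc length s in [0, perimeter) of the
    projection; s = 0 at parametric angle 0 (major-axis direction).
    """
    xy = np.atleast_2d(np.asarray(positions, dtype=float))
    rel = xy - np.asarray(ellipse.center)
    c, s = np.cos(ellipse.rotation), np.sin(ellipse.rotation)
    xr = c * rel[:, 0] + s * rel[:, 1]
    yr = -s * rel[:, 0] + c * rel[:, 1]
    r = np.hypot(xr, yr)
    if np.any(r < 1e-9 * ellipse.b):
        raise ProjectionError("point at the ellipse center has no radial projection")
    t = np.mod(np.arctan2(ellipse.a * yr, ellipse.b * xr), 2 * np.pi)
    return ellipse.arc_length(t)


def count_laps(linear_series: np.ndarray, perimeter: float) -> int:
    """Number of full circuits of the track.

    The circular coordinate is unwrapped as a phase and the lap count is the
    net unwrapped excursion in units of the perimeter, floored; back-and-forth
    excursions below a full circuit contribute nothing.
    """
    s = np.asarray(linear_series, dtype=float)
    if s.size < 2:
        return 0
    phase = np.unwrap(2 * np.pi * s / perimeter)
    # tolerance absorbs roundoff when a circuit closes exactly on its start
    return int(np.floor(abs(phase[-1] - phase[0]) / (2 * np.pi) + 1e-7))
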