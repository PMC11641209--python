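"""Orthogonal plane fitting and bilateral-distance geometry.

The central anatomical summary of an amphid layout is the acute dihedral
angle between the two orthogonal-least-squares planes fitted to the nuclear
centroids of the left and the right half.  The plane for one side minimises
the sum of squared perpendicular distances of the nuclei to the plane; its
normal is the smallest principal axis of the centred point cloud.  Distances
between the left and right member of a bilateral neuron pair are plain
Euclidean distances in the same frame.

Points are arrays of shape ``(n, 3)`` with columns ``(ap, dv, ml)`` in µm,
in the frame defined in :mod:`amphid.template`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DegenerateGeometryError, InsufficientPointsError, ValidationError

__all__ = [
    "PlaneFit",
    "PlaneFitter",
    "fit_plane",
    "plane_angle",
    "bilateral_distance",
    "dihedral_opening",
]


@dataclass(frozen=True)
class PlaneFit:
    """Result of an orthogonal-least-squares plane fit.

    Attributes
    ----------
    normal
        Unit normal of the plane, canonically oriented: the ML component is
        non-negative; ties are broken by a non-negative DV, then AP,
        component.
    centroid
        Mean of the fitted points (the plane passes through it).
    rms_residual
        Root-mean-square perpendicular distance of the points to the plane,
        in µm.  Zero iff the points are exactly coplanar.
    n_points
        Number of points used in the fit.
    """

    normal: np.ndarray
    centroid: np.ndarray
    rms_residual: float
    n_points: int


def _canonical_normal(n: np.ndarray) -> np.ndarray:
    """Orient a unit normal so (ml, dv, ap) is lexicographically >= 0."""
    ml, dv, ap = n[2], n[1], n[0]
    if ml < 0 or (ml == 0 and (dv < 0 or (dv == 0 and ap < 0))):
        return -n
    return n


class PlaneFitter(BaseEstimator):
    """Orthogonal-least-squares plane estimator for a 3D point cloud.

    The fitted plane minimises the summed squared perpendicular distances of
    the points, obtained in closed form from the SVD of the centred
    coordinates: the normal is the right singular vector of the smallest
    singular value.

    Parameters
    ----------
    collinearity_tol : float, default 1e-10
        A configuration of points is rejected as collinear when the ratio of
        the second-smallest to the largest singular value of the centred
        coordinates falls below this tolerance.

    Attributes
    ----------
    normal_ : ndarray of shape (3,)
        Canonically oriented unit normal.
    centroid_ : ndarray of shape (3,)
        Centroid of the input points.
    rms_residual_ : float
        RMS perpendicular distance, µm.
    n_points_ : int
        Number of points fitted.
    singular_values_ : ndarray of shape (3,)
        Singular values of the centred coordinates, descending.
    """

    def __init__(self, collinearity_tol: float = 1e-10):
        self.collinearity_tol = collinearity_tol

    def fit(self, X, y=None) -> "PlaneFitter":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValidationError(f"expected an (n, 3) point array, got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValidationError("points contain non-finite coordinates")
        n = X.shape[0]
        if n < 3:
            raise InsufficientPointsError(f"plane fit requires >= 3 points, got {n}")
        centroid = X.mean(axis=0)
        centered = X - centroid
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] == 0 or s[1] / s[0] < self.collinearity_tol:
            raise DegenerateGeometryError(
                "points are collinear (or coincident); the plane is not determined"
            )
        self.normal_ = _canonical_normal(vt[2])
        self.centroid_ = centroid
        self.rms_residual_ = float(s[2] / np.sqrt(n))
        self.n_points_ = int(n)
        self.singular_values_ = s
        return self

    def transform(self, X) -> np.ndarray:
        """Signed perpendicular distances of points to the fitted plane (µm)."""
        X = np.asarray(X, dtype=float)
        return (X - self.centroid_) @ self.normal_

    def result_(self) -> PlaneFit:
        """The fit as an immutable :class:`PlaneFit` record."""
        return PlaneFit(
            normal=self.normal_,
            centroid=self.centroid_,
            rms_residual=self.rms_residual_,
            n_points=self.n_points_,
        )


def fit_plane(points, collinearity_tol: float = 1e-10) -> PlaneFit:
    """Fit the orthogonal-least-squares plane to ``points`` ((n, 3) array)."""
    return PlaneFitter(collinearity_tol=collinearity_tol).fit(points).result_()


def plane_angle(a: PlaneFit, b: PlaneFit) -> float:
    """Acute dihedral angle between two fitted planes, in degrees [0, 90].

    Computed as ``arccos(|n_a . n_b|)``; symmetric in its arguments and
    independent of normal orientation.
    """
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def bilateral_distance(left, right) -> float:
    """Euclidean distance (µm) between the two members of a bilateral pair."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if not (np.isfinite(left).all() and np.isfinite(right).all()):
        raise ValidationError("bilateral_distance requires finite coordinates")
    return float(np.linalg.norm(left - right))


def dihedral_opening(a: PlaneFit, b: PlaneFit, parallel_tol_deg: float = 1e-6) -> str:
    """Which way the wedge between two side planes opens.

    Returns ``"ventral"`` when the planes' intersection line lies dorsal to
    the joint centroid (the halves meet dorsally and spread ventrally, the
    pattern seen in tilted layouts), ``"dorsal"`` for the opposite, and
    ``"parallel"`` when the planes do not measurably intersect.
    """
    n1, n2 = a.normal, b.normal
    d = np.cross(n1, n2)
    nd = np.linalg.norm(d)
    if plane_angle(a, b) < parallel_tol_deg or nd < 1e-12:
        return "parallel"
    d = d / nd
    # Point on the intersection line: solve n1.x = n1.c1, n2.x = n2.c2 in the
    # plane spanned by n1, n2.
    A = np.array([n1, n2])
    rhs = np.array([np.dot(n1, a.centroid), np.dot(n2, b.centroid)])
    x0, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    mid = (a.centroid + b.centroid) / 2.0
    # Closest point of the line to the joint centroid.
    closest = x0 + np.dot(mid - x0, d) * d
    return "ventral" if closest[1] > mid[1] else "dorsal"
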