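"""Core spherical geometry and nondimensionalization.

Every quantity downstream is built on three primitives: geodesic
(great-circle) distance on a sphere of radius ``R``, the average occupied
length scale ``L_av`` — the hexagon-equivalent diameter of the mean area
per cell — and the effective hard-disk area fraction
``phi = (pi / (2 sqrt(3))) * x_min**2`` implied by a minimum
nondimensional center-to-center distance ``x_min``.

``L_av`` is defined as ``sqrt((4 pi R^2 / N) * (2 / sqrt(3)))``: the
diameter of the disk inscribed in a regular hexagon whose area equals the
per-cell share of the sphere surface ``4 pi R^2 / N``.  With this choice
the area fraction of disks of diameter ``x_min * L_av`` reduces exactly to
the hexagonal-packing form above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpherePoints",
    "geodesic_distance",
    "project_to_sphere",
    "average_occupied_length",
    "effective_area_fraction",
    "tangent_frame",
    "pairwise_geodesic_distances",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class SpherePoints:
    """``N`` unit direction vectors plus a physical sphere radius ``R``.

    ``coords`` holds unit vectors; physical positions are ``R * coords``.
    ``center`` records the sphere center the points were projected from
    (zeros for simulated data).
    """

    coords: np.ndarray
    R: float = 1.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if coords.shape[0] < 1:
            raise ValueError("need at least one point")
        if self.R <= 0:
            raise ValueError(f"radius must be positive, got {self.R}")
        norms = np.linalg.norm(coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("coords must be unit vectors (tolerance 1e-6)")
        # renormalize to machine precision so the 1e-9 invariant holds
        object.__setattr__(self, "coords", coords / norms[:, None])
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def N(self) -> int:
        return self.coords.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """Physical coordinates ``center + R * coords``."""
        return self.center + self.R * self.coords


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if not np.all(np.abs(norm - 1.0) < 1e-6):
        raise ValueError(f"{name} must be a unit vector")
    return v


def geodesic_distance(a: np.ndarray, b: np.ndarray, R: float = 1.0) -> float | np.ndarray:
    """Great-circle distance ``R * arccos(a . b)`` between unit vectors.

    Accepts broadcastable arrays of unit vectors in the last axis.  The dot
    product is clamped to [-1, 1] so coincident or antipodal pairs are safe
    against floating-point overshoot.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    a = _check_unit(a, "a")
    b = _check_unit(b, "b")
    dot = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    return R * np.arccos(dot)


def pairwise_geodesic_distances(points: SpherePoints) -> np.ndarray:
    """Condensed upper-triangle vector of all pairwise geodesic distances."""
    gram = np.clip(points.coords @ points.coords.T, -1.0, 1.0)
    iu = np.triu_indices(points.N, k=1)
    return points.R * np.arccos(gram[iu])


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (linearized) least-squares sphere fit.

    Solves ``|p|^2 = 2 c . p + (r^2 - |c|^2)`` for center ``c`` and radius
    ``r``; closed-form and deterministic, adequate for near-spherical
    shells of nuclear centroids.
    """
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit degenerate: nonpositive squared radius")
    return center, float(np.sqrt(r2))


def project_to_sphere(raw_points: np.ndarray, center="fit") -> SpherePoints:
    """Radially project 3D points onto a sphere.

    Parameters
    ----------
    raw_points
        (N, 3) coordinates, e.g. nuclear centroids in micrometres.
    center
        Projection center: a 3-vector, or ``"fit"`` (default) to estimate
        center and radius by a least-squares sphere fit (requires at least
        4 points not all coplanar).

    The fitted (or mean-distance) radius is stored on the result so all
    geodesic distances come out in the input units.
    """
    raw_points = np.asarray(raw_points, dtype=float)
    if raw_points.ndim != 2 or raw_points.shape[1] != 3:
        raise ValueError("raw_points must be (N, 3)")
    if isinstance(center, str):
        if center != "fit":
            raise ValueError(f"unknown center mode {center!r}")
        if len(raw_points) < 4:
            raise ValueError("sphere fit needs at least 4 points")
        c, R = _fit_sphere(raw_points)
    else:
        c = np.asarray(center, dtype=float)
        R = None
    rel = raw_points - c
    norms = np.linalg.norm(rel, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        raise ValueError(f"point {bad[0]} coincides with the projection center")
    if R is None:
        R = float(norms.mean())
    return SpherePoints(coords=rel / norms[:, None], R=R, center=c)


def average_occupied_length(N: int, R: float = 1.0) -> float:
    """Average occupied length scale L_av = sqrt((4 pi R^2 / N) (2 / sqrt 3)).

    The diameter of the hexagon-equivalent disk for the average surface
    area each of the ``N`` cells occupies; scales as ``R / sqrt(N)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if R <= 0:
        raise ValueError("R must be positive")
    area_per_cell = 4.0 * np.pi * R * R / N
    return float(np.sqrt(area_per_cell * 2.0 / np.sqrt(3.0)))


def effective_area_fraction(x_min: float) -> float:
    """Effective hard-disk area fraction phi = (pi / (2 sqrt 3)) x_min^2.

    ``x_min = 1`` gives the planar hexagonal close-packing bound
    ``pi / (2 sqrt 3) ~= 0.9069``.
    """
    if x_min < 0:
        raise ValueError("x_min must be nonnegative")
    return float(np.pi / (2.0 * np.sqrt(3.0)) * x_min * x_min)


def tangent_frame(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangent basis (e1, e2) at unit vector p.

    e1 is the normalized projection of the global axis least aligned with
    p into the tangent plane; e2 = p x e1.  Used as the reference frame
    for bond angles in the psi6 computation (only |psi6| is
    frame-independent, which is all that is ever compared).
    """
    p = _check_unit(p, "p")
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(p)))] = 1.0
    e1 = helper - (helper @ p) * p
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    return e1, e2
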