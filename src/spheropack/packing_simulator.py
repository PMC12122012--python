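"""Minimum-distance particle packings on a sphere.

Random sequential adsorption (RSA): particles are inserted one at a time
at area-uniform candidate positions and a candidate is rejected whenever
it lies within geodesic distance ``D_p_min = x_min * L_av(N, R)`` of any
already-placed particle.  With ``x_min = 0`` this reduces to i.i.d.
uniform sampling on the sphere.  RSA on a surface saturates near area
fraction ~0.547, so configurations with implied
``phi = (pi/(2 sqrt 3)) x_min^2`` approaching that value may need many
attempts or fail; a failed run discards all points and restarts with a
fresh random stream to avoid bias from jammed partial configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from spheropack.sphere_geometry import SpherePoints, average_occupied_length, effective_area_fraction

__all__ = [
    "PackingConfig",
    "InfeasiblePackingError",
    "sample_uniform_sphere",
    "simulate_min_distance_packing",
    "pack_ensemble",
]

# empirical RSA saturation coverage for disks (flat-space value; curvature
# shifts it only slightly at the N used here)
RSA_SATURATION_PHI = 0.547


class InfeasiblePackingError(RuntimeError):
    """Raised when RSA cannot place all N particles within the attempt budget."""

    def __init__(self, requested: int, achieved: int, x_min: float):
        self.requested = requested
        self.achieved = achieved
        self.x_min = x_min
        super().__init__(
            f"could not place {requested} particles at x_min={x_min:g}; "
            f"best attempt achieved {achieved}"
        )


@dataclass(frozen=True)
class PackingConfig:
    """Parameters of one minimum-distance packing run.

    ``relax_sweeps = 0`` (the default) gives plain RSA.  A positive value
    applies that many constraint-guarded Lloyd (centroidal Voronoi)
    sweeps after insertion: each point moves toward the centroid of its
    Voronoi cell, and any move that would violate the minimum-distance
    constraint is rejected.  This emulates the space-filling tendency of
    confluent epithelia, whose neighbor-distance spread is far narrower
    than an RSA gas; see the synthetic-tissue generator, which enables
    it.
    """

    N: int
    x_min: float = 0.0
    R: float = 1.0
    seed: int = 0
    max_attempts_per_particle: int = 10_000
    max_restarts: int = 10
    relax_sweeps: int = 0
    relax_damp: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.x_min < 0:
            raise ValueError("x_min must be nonnegative")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.relax_sweeps < 0 or not 0 < self.relax_damp <= 1:
            raise ValueError("relax_sweeps must be >= 0 and relax_damp in (0, 1]")
        phi = effective_area_fraction(self.x_min)
        if phi >= RSA_SATURATION_PHI:
            warnings.warn(
                f"implied area fraction phi={phi:.3f} is at or beyond the "
                f"~{RSA_SATURATION_PHI} RSA saturation coverage; sequential "
                "insertion may fail",
                stacklevel=2,
            )

    @property
    def min_distance(self) -> float:
        """Physical exclusion distance D_p_min = x_min * L_av(N, R)."""
        return self.x_min * average_occupied_length(self.N, self.R)


def sample_uniform_sphere(N: int, R: float = 1.0, seed: int = 0) -> SpherePoints:
    """N i.i.d. area-uniform points on a sphere of radius R.

    Uses normalized standard Gaussians; reproducible for a fixed seed.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((N, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SpherePoints(coords=v, R=R)


def _rsa_attempt(
    N: int, cos_thresh: float, rng: np.random.Generator, max_attempts: int, batch: int = 256
) -> np.ndarray | None:
    """One full RSA insertion pass; returns (N, 3) unit vectors or None."""
    pts = np.empty((N, 3))
    n_placed = 0
    while n_placed < N:
        attempts = 0
        placed = False
        while attempts < max_attempts:
            k = min(batch, max_attempts - attempts)
            cand = rng.standard_normal((k, 3))
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            if n_placed == 0:
                pts[0] = cand[0]
                placed = True
                break
            # candidate is valid iff no existing point is closer than the
            # exclusion distance, i.e. all dot products <= cos_thresh
            ok = np.all(cand @ pts[:n_placed].T <= cos_thresh, axis=1)
            idx = np.flatnonzero(ok)
            if idx.size:
                pts[n_placed] = cand[idx[0]]
                placed = True
                break
            attempts += k
        if not placed:
            return pts[:n_placed]
        n_placed += 1
    return pts


def lloyd_relax(points: SpherePoints, d_min: float, sweeps: int, damp: float = 1.0) -> SpherePoints:
    """Constraint-guarded Lloyd relaxation on the sphere.

    Each sweep moves every point a fraction ``damp`` of the way toward
    the (area-weighted) centroid of its spherical Voronoi cell,
    re-projected to the sphere; moves are accepted sequentially and any
    move that would bring the point within geodesic distance ``d_min`` of
    another is rejected, so the minimum-distance postcondition is
    preserved exactly.  The step is deterministic (no randomness).
    """
    from spheropack.tessellation import spherical_voronoi

    X = points.coords.copy()
    cos_thresh = float(np.cos(d_min / points.R)) if d_min > 0 else 2.0
    n = len(X)
    for _ in range(sweeps):
        tess = spherical_voronoi(SpherePoints(coords=X, R=points.R))
        # vectorized fan-triangle centroids: cell i's centroid is the
        # normalized area-weighted mean of triangles (p_i, v_k, v_k+1)
        cell_idx, v1_idx, v2_idx = [], [], []
        for i, ring in enumerate(tess.regions):
            m = len(ring)
            for k in range(m):
                cell_idx.append(i)
                v1_idx.append(ring[k])
                v2_idx.append(ring[(k + 1) % m])
        cell_idx = np.asarray(cell_idx)
        P = X[cell_idx]
        V1 = tess.vertices[v1_idx]
        V2 = tess.vertices[v2_idx]
        w = np.linalg.norm(np.cross(V1 - P, V2 - P), axis=1)
        contrib = w[:, None] * (P + V1 + V2)
        cent = np.zeros((n, 3))
        np.add.at(cent, cell_idx, contrib)
        cent /= np.linalg.norm(cent, axis=1, keepdims=True)
        targets = X + damp * (cent - X)
        targets /= np.linalg.norm(targets, axis=1, keepdims=True)
        for i in range(n):  # sequential acceptance keeps the constraint exact
            d = X @ targets[i]
            d[i] = -2.0
            if d.max() <= cos_thresh:
                X[i] = targets[i]
    return SpherePoints(coords=X, R=points.R)


def simulate_min_distance_packing(cfg: PackingConfig) -> SpherePoints:
    """Generate N particles on the sphere with pairwise geodesic distances
    >= x_min * L_av via random sequential adsorption, optionally followed
    by ``cfg.relax_sweeps`` constraint-guarded Lloyd sweeps.

    Deterministic for a fixed ``cfg.seed``.  Raises
    :class:`InfeasiblePackingError` (reporting the best achieved count) if
    the attempt/restart budget is exhausted.
    """
    d_min = cfg.min_distance
    if d_min > np.pi * cfg.R:
        raise InfeasiblePackingError(cfg.N, 1 if cfg.N >= 1 else 0, cfg.x_min)
    if cfg.x_min == 0.0:
        result_pts = sample_uniform_sphere(cfg.N, cfg.R, cfg.seed)
    else:
        cos_thresh = float(np.cos(d_min / cfg.R))
        rng = np.random.default_rng(cfg.seed)
        best = 0
        result_pts = None
        for _ in range(cfg.max_restarts):
            result = _rsa_attempt(cfg.N, cos_thresh, rng, cfg.max_attempts_per_particle)
            if result is not None and len(result) == cfg.N:
                result_pts = SpherePoints(coords=result, R=cfg.R)
                break
            if result is not None:
                best = max(best, len(result))
        if result_pts is None:
            raise InfeasiblePackingError(cfg.N, best, cfg.x_min)
    if cfg.relax_sweeps > 0 and cfg.N >= 4:
        result_pts = lloyd_relax(result_pts, d_min, cfg.relax_sweeps, cfg.relax_damp)
    return result_pts


def pack_ensemble(cfg: PackingConfig, replicates: int) -> list[SpherePoints]:
    """Independent packings with derived seeds ``cfg.seed + k``, k = 0..replicates-1."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from dataclasses import replace

    out = []
    for k in range(replicates):
        out.append(simulate_min_distance_packing(replace(cfg, seed=cfg.seed + k)))
    return out
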