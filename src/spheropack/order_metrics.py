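"""Pair-distance statistics, bond-orientational order and g(s).

Distances between Voronoi-adjacent cells are nondimensionalized by the
average occupied length ``L_av(N, R)`` to give ``x = D_c / L_av``; the
estimator ``mean(x) - 3 sd(x)`` recovers the minimum distance scale
``x_min`` of a packing from its neighbor-distance distribution.

The bond-orientational order per cell is the standard local hexatic
order with Voronoi neighbors,

    psi6_i = (1 / z_i) sum_j exp(i 6 theta_ij),

with bond angles theta_ij measured in the tangent plane at cell i against
a fixed tangent frame; only the modulus |psi6_i| is frame- and
rotation-invariant on a sphere, so only magnitudes are reported.

The geodesic radial distribution function g(s) normalizes observed pair
counts per distance bin by the expectation for area-uniform points,
``(N(N-1)/2) * integral_bin sin(s/R) / (2R) ds``, so an ideal-gas
(unconstrained) configuration gives g = 1 in every bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spheropack.sphere_geometry import (
    SpherePoints,
    average_occupied_length,
    pairwise_geodesic_distances,
    tangent_frame,
)
from spheropack.tessellation import VoronoiTessellation

__all__ = [
    "PairDistanceSet",
    "XminEstimate",
    "Psi6Result",
    "RadialDistribution",
    "neighbor_distances",
    "estimate_xmin",
    "psi6",
    "radial_distribution",
    "ensemble_radial_distribution",
]


@dataclass(frozen=True)
class PairDistanceSet:
    """Geodesic pair distances D_c and their dimensionless form x = D_c / L_av."""

    distances: np.ndarray
    x: np.ndarray
    L_av: float
    scope: str = "neighbors"  # "neighbors" (Voronoi-adjacent) or "all_pairs"


@dataclass(frozen=True)
class XminEstimate:
    """mean - 3 s.d. estimate of the minimum dimensionless distance."""

    x_min: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class Psi6Result:
    per_cell: np.ndarray  # |psi6_i| in [0, 1]
    mean: float  # <|psi6|> over cells


@dataclass(frozen=True)
class RadialDistribution:
    """Binned g over geodesic distance s in (0, pi R].

    ``counts`` are per-replicate mean pair counts; ``n_replicates`` is 1
    for a single configuration and the ensemble size after averaging.
    """

    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    N: int
    R: float
    n_replicates: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def expected_uniform_counts(self) -> np.ndarray:
        """Per-replicate expected pair count per bin for area-uniform points."""
        n_pairs = self.N * (self.N - 1) / 2
        s = np.clip(self.bin_edges, 0, np.pi * self.R)
        return n_pairs * np.diff(0.5 * (1.0 - np.cos(s / self.R)))


def neighbor_distances(points: SpherePoints, tess: VoronoiTessellation) -> PairDistanceSet:
    """Geodesic distances between Voronoi-adjacent pairs, each counted once."""
    if tess.points is not points and tess.N != points.N:
        raise ValueError("tessellation does not match the given points")
    coords = points.coords
    pairs = [(i, j) for i, nbrs in enumerate(tess.neighbors) for j in nbrs if i < j]
    idx = np.array(pairs)
    dots = np.clip(np.einsum("ij,ij->i", coords[idx[:, 0]], coords[idx[:, 1]]), -1, 1)
    d = points.R * np.arccos(dots)
    L_av = average_occupied_length(points.N, points.R)
    return PairDistanceSet(distances=d, x=d / L_av, L_av=L_av, scope="neighbors")


def estimate_xmin(pair_set: PairDistanceSet) -> XminEstimate:
    """Estimate x_min as mean(x) - 3 sd(x) with the sample (n-1) s.d."""
    x = np.asarray(pair_set.x, dtype=float)
    if x.size < 2:
        raise ValueError("estimate_xmin needs at least 2 distances")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return XminEstimate(x_min=mean - 3.0 * sd, mean=mean, sd=sd, n=x.size)


def psi6(points: SpherePoints, tess: VoronoiTessellation) -> Psi6Result:
    """Per-cell |psi6| and its mean over cells, using Voronoi neighbors.

    Each neighbor direction is projected into the tangent plane at the
    cell and its angle measured against the deterministic tangent frame.
    A neighbor antipodal to the cell has no tangent projection and raises
    ``ValueError``.
    """
    coords = points.coords
    mags = np.empty(points.N)
    for i in range(points.N):
        p = coords[i]
        nbrs = tess.neighbors[i]
        if len(nbrs) == 0:
            raise ValueError(f"cell {i} has no neighbors")
        e1, e2 = tangent_frame(p)
        v = coords[nbrs] - np.outer(coords[nbrs] @ p, p)
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError(f"cell {i} has a neighbor antipodal to it; tangent projection degenerate")
        theta = np.arctan2(v @ e2, v @ e1)
        mags[i] = np.abs(np.mean(np.exp(6j * theta)))
    return Psi6Result(per_cell=mags, mean=float(mags.mean()))


def _uniform_pair_cdf(s: np.ndarray, R: float) -> np.ndarray:
    """P(geodesic distance <= s) for two independent uniform points: (1 - cos(s/R)) / 2."""
    return 0.5 * (1.0 - np.cos(s / R))


def radial_distribution(points: SpherePoints, bin_width: float | str = "auto") -> RadialDistribution:
    """Geodesic radial distribution function g(s) over all pairs.

    Bins cover (0, pi R]; ``bin_width="auto"`` uses 0.1 * L_av(N, R).
    Normalized so that area-uniform points give g -> 1 in every bin, and
    the binned counts sum to exactly N(N-1)/2.
    """
    if points.N < 2:
        raise ValueError("radial_distribution needs at least 2 points")
    R = points.R
    if isinstance(bin_width, str):
        if bin_width != "auto":
            raise ValueError(f"unknown bin_width mode {bin_width!r}")
        bin_width = 0.1 * average_occupied_length(points.N, R)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(np.pi * R / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    edges[-1] = max(edges[-1], np.pi * R * (1 + 1e-12))  # include s = pi R

    d = pairwise_geodesic_distances(points)
    counts, _ = np.histogram(d, bins=edges)
    n_pairs = points.N * (points.N - 1) // 2
    expected = n_pairs * np.diff(_uniform_pair_cdf(np.clip(edges, 0, np.pi * R), R))
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RadialDistribution(bin_edges=edges, g=g, counts=counts, N=points.N, R=R)


def ensemble_radial_distribution(
    samples: list[SpherePoints], bin_width: float | str = "auto"
) -> RadialDistribution:
    """Average of per-replicate g values over an ensemble (not pooled counts).

    All samples must share N and R so bins coincide.
    """
    if not samples:
        raise ValueError("ensemble must be non-empty")
    first = radial_distribution(samples[0], bin_width)
    gs = [first.g]
    counts = first.counts.astype(float)
    for s in samples[1:]:
        if s.N != first.N or s.R != first.R:
            raise ValueError("ensemble samples must share N and R")
        rd = radial_distribution(s, bin_width)
        gs.append(rd.g)
        counts += rd.counts
    return RadialDistribution(
        bin_edges=first.bin_edges,
        g=np.mean(gs, axis=0),
        counts=counts / len(samples),
        N=first.N,
        R=first.R,
        n_replicates=len(samples),
    )
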