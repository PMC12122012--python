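"""Spherical Voronoi tessellation and neighbor-order topology.

For points on a sphere the Voronoi diagram is the dual of the Delaunay
triangulation, which coincides with the convex hull of the points.  Two
generators are Voronoi neighbors iff they share a hull edge; the Voronoi
vertices are the (spherical) circumcenters of the hull facets, i.e. the
outward facet normals.  The per-cell vertex count z_i therefore equals
the neighbor count, and Euler's polyhedron formula forces

    sum_i (6 - z_i) = 12        and        z_av = 6 - 12/N

for every configuration — the topological charge of the sphere.

Degenerate configurations in which four or more cells meet at a vertex
(e.g. the cube's generators, whose dual vertices are 4-valent) are
resolved deterministically by qhull's facet triangulation: each k-valent
vertex splits into k-2 coincident trivalent vertices joined by
zero-length edges, which is equivalent to an infinitesimal symbolic
perturbation of the generators.  ``verify_topology`` reports how many
such vertices were resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from spheropack.sphere_geometry import SpherePoints, tangent_frame

__all__ = [
    "VoronoiTessellation",
    "NeighborOrderSummary",
    "TopologyReport",
    "spherical_voronoi",
    "neighbor_order_summary",
    "verify_topology",
]

_COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class VoronoiTessellation:
    """Spherical Voronoi tessellation of N generators.

    Attributes
    ----------
    points : the generators.
    neighbors : per-cell sorted arrays of neighbor indices (symmetric).
    z : per-cell neighbor count = Voronoi polygon vertex count.
    vertices : (V, 3) unit vectors of Voronoi vertices (Delaunay facet
        circumcenters); coincident entries encode resolved degeneracies.
    regions : per-cell lists of vertex indices ordered counterclockwise
        around the generator.
    areas : per-cell spherical polygon area, in steradians times R^2.
    """

    points: SpherePoints
    neighbors: list
    z: np.ndarray
    vertices: np.ndarray
    regions: list
    areas: np.ndarray

    @property
    def N(self) -> int:
        return self.points.N

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return int(self.z.sum()) // 2

    @property
    def n_faces(self) -> int:
        return self.N

    @property
    def z_av(self) -> float:
        return float(self.z.mean())


@dataclass(frozen=True)
class NeighborOrderSummary:
    """Fractions of cells with z < 6, z = 6, z > 6, plus the mean z."""

    f_lt6: float
    f_6: float
    f_gt6: float
    z_av: float
    N: int

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_lt6, self.f_6, self.f_gt6])


@dataclass(frozen=True)
class TopologyReport:
    euler_ok: bool
    trivalent_ok: bool
    charge_ok: bool
    symmetric_ok: bool
    V: int
    E: int
    F: int
    topological_charge: int
    n_degenerate_vertices: int


def _spherical_triangle_excess(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Area (spherical excess) of the triangle a,b,c via l'Huilier's formula."""
    sa = np.arccos(np.clip(b @ c, -1, 1))
    sb = np.arccos(np.clip(a @ c, -1, 1))
    sc = np.arccos(np.clip(a @ b, -1, 1))
    s = 0.5 * (sa + sb + sc)
    t = (
        np.tan(s / 2)
        * np.tan((s - sa) / 2)
        * np.tan((s - sb) / 2)
        * np.tan((s - sc) / 2)
    )
    return float(4.0 * np.arctan(np.sqrt(max(t, 0.0))))


def spherical_voronoi(points: SpherePoints) -> VoronoiTessellation:
    """Build the spherical Voronoi tessellation of the given points.

    Requires N >= 4 generators, no two coincident.  Raises ``ValueError``
    naming the offending pair on coincident generators.
    """
    coords = points.coords
    n = points.N
    if n < 4:
        raise ValueError("spherical Voronoi needs at least 4 generators")
    close = cKDTree(coords).query_pairs(_COINCIDENT_TOL)
    if close:
        i, j = sorted(next(iter(close)))
        raise ValueError(f"generators {i} and {j} are coincident within {_COINCIDENT_TOL}")

    hull = ConvexHull(coords)
    simplices = hull.simplices  # (T, 3) generator indices per Delaunay triangle
    # spherical circumcenter of each facet = outward unit facet normal
    normals = hull.equations[:, :3]
    vertices = normals / np.linalg.norm(normals, axis=1, keepdims=True)

    # adjacency: generators sharing a Delaunay edge
    neighbor_sets: list[set] = [set() for _ in range(n)]
    incident: list[list[int]] = [[] for _ in range(n)]
    for t, (a, b, c) in enumerate(simplices):
        neighbor_sets[a].update((b, c))
        neighbor_sets[b].update((a, c))
        neighbor_sets[c].update((a, b))
        incident[a].append(t)
        incident[b].append(t)
        incident[c].append(t)

    neighbors = [np.array(sorted(s), dtype=int) for s in neighbor_sets]
    z = np.array([len(s) for s in neighbor_sets], dtype=int)

    # order each cell's incident circumcenters counterclockwise around the
    # generator to get the Voronoi polygon, and accumulate its area
    regions: list[list[int]] = []
    areas = np.empty(n)
    for i in range(n):
        p = coords[i]
        e1, e2 = tangent_frame(p)
        tris = incident[i]
        vecs = vertices[tris] - np.outer(vertices[tris] @ p, p)
        ang = np.arctan2(vecs @ e2, vecs @ e1)
        order = np.argsort(ang)
        ring = [tris[k] for k in order]
        regions.append(ring)
        area = 0.0
        m = len(ring)
        for k in range(m):
            v1 = vertices[ring[k]]
            v2 = vertices[ring[(k + 1) % m]]
            area += _spherical_triangle_excess(p, v1, v2)
        areas[i] = area * points.R**2

    return VoronoiTessellation(
        points=points,
        neighbors=neighbors,
        z=z,
        vertices=vertices,
        regions=regions,
        areas=areas,
    )


def neighbor_order_summary(tess: VoronoiTessellation) -> NeighborOrderSummary:
    """Classify cells into z < 6, z = 6, z > 6 and report fractions."""
    z = tess.z
    n = len(z)
    return NeighborOrderSummary(
        f_lt6=float(np.mean(z < 6)),
        f_6=float(np.mean(z == 6)),
        f_gt6=float(np.mean(z > 6)),
        z_av=float(z.mean()),
        N=n,
    )


def verify_topology(tess: VoronoiTessellation) -> TopologyReport:
    """Check the Euler identities of the tessellation.

    Asserts V - E + F = 2, 3V = 2E (trivalent vertices after degeneracy
    resolution) and the topological charge sum(6 - z_i) = 12; reports the
    number of degenerate (4+-valent) Voronoi vertices that were resolved
    by triangulation, identified as groups of coincident circumcenters.
    Raises ``AssertionError`` if any identity fails.
    """
    V, E, F = tess.n_vertices, tess.n_edges, tess.n_faces
    charge = int(np.sum(6 - tess.z))
    euler_ok = V - E + F == 2
    trivalent_ok = 3 * V == 2 * E
    charge_ok = charge == 12
    symmetric_ok = all(
        i in tess.neighbors[j] for i, nbrs in enumerate(tess.neighbors) for j in nbrs
    )
    # coincident circumcenters mark degenerate vertices split by triangulation
    groups = cKDTree(tess.vertices).query_pairs(1e-7)
    merged: dict[int, set] = {}
    for a, b in groups:
        merged.setdefault(a, {a}).add(b)
    n_degenerate = len({frozenset(s) for s in merged.values()})
    report = TopologyReport(
        euler_ok=euler_ok,
        trivalent_ok=trivalent_ok,
        charge_ok=charge_ok,
        symmetric_ok=symmetric_ok,
        V=V,
        E=E,
        F=F,
        topological_charge=charge,
        n_degenerate_vertices=n_degenerate,
    )
    if not (euler_ok and trivalent_ok and charge_ok and symmetric_ok):
        raise AssertionError(f"tessellation violates a topological identity: {report}")
    return report
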