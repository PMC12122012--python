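"""Structural gas/liquid classification and the phase diagram.

A packing is "liquid-like" once its ensemble-averaged geodesic radial
distribution function develops a first peak — short-range structure — and
"gas-like" (ideal-gas-flat g) below that.  Scanning the minimum distance
x_min at fixed N gives the critical x_c(N); the set of (N, x_c) pairs is
the gas-liquid boundary.  An alternative boundary uses the coordination
number: the mean number of neighbors within the first minimum of g after
the first peak.  Compositions (f_{z<6}, f_{z=6}, f_{z>6}) live on a
ternary simplex, where growth trajectories can be overlaid on the
boundary.

Peak detection rule: the smallest-s local maximum of g whose height
exceeds 1 and whose prominence over both flanking minima is at least
``prominence`` (default 0.1).  The threshold is fixed so that
unconstrained (x_min = 0) ensembles of any size read as gas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from spheropack.order_metrics import RadialDistribution, ensemble_radial_distribution
from spheropack.packing_simulator import PackingConfig, pack_ensemble
from spheropack.sphere_geometry import geodesic_distance
from spheropack.tessellation import NeighborOrderSummary, neighbor_order_summary, spherical_voronoi

__all__ = [
    "PhaseDiagram",
    "detect_first_peak",
    "critical_xmin",
    "coordination_boundary",
    "compute_phase_diagram",
    "ternary_map",
    "classify_phase",
    "trajectory_span",
    "TrajectorySpans",
]

# ternary simplex corners in 2D: z<6 bottom-left, z=6 bottom-right, z>6 top
_TERNARY_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass(frozen=True)
class PhaseDiagram:
    """Mean neighbor-order compositions over an (N, x_min) grid plus the boundary x_c(N)."""

    N_values: np.ndarray
    xmin_values: np.ndarray
    fractions: np.ndarray  # (len(N), len(xmin), 3) mean (f_lt6, f_6, f_gt6)
    x_c: np.ndarray  # per-N critical x_min (nan where undefined)
    replicates: int
    seed: int


class BoundaryUndefinedError(RuntimeError):
    """No first peak of g(s) appears anywhere on the scanned x_min grid."""


def _first_peak_index(rd: RadialDistribution, prominence: float):
    """Bin index of the first significant peak of g, or None.

    A peak is the smallest-s local maximum with height > 1 whose
    prominence over the higher of its flanking minima is >= ``prominence``.
    Because g is a ratio of Poisson counts, every bin fluctuates with
    standard error ~1/sqrt(expected pairs); a candidate peak is therefore
    additionally required to exceed 1 by at least 4.5 times its counting
    standard error.  A phase-diagram scan inspects thousands of bins, so
    Bonferroni control of false peaks at the scan scale needs ~4.2
    standard errors; genuine liquid-structure first peaks exceed 1 by
    >~15 standard errors at every tested size, so the guard costs no
    sensitivity.
    """
    g = np.asarray(rd.g, dtype=float)
    peaks, _ = find_peaks(g, prominence=prominence, height=1.0 + 1e-12)
    if peaks.size == 0:
        return None
    expected = rd.expected_uniform_counts() * rd.n_replicates
    pooled = np.asarray(rd.counts, dtype=float) * rd.n_replicates
    for p in peaks:
        if expected[p] <= 0:
            continue
        sigma = np.sqrt(max(pooled[p], 1.0)) / expected[p]
        if g[p] - 1.0 >= 4.5 * sigma:
            return int(p)
    return None


def detect_first_peak(rd: RadialDistribution, prominence: float = 0.1):
    """Location (bin-center s) of the first peak of g, or None."""
    if np.count_nonzero(rd.counts) < 10:
        raise ValueError("radial distribution must have at least 10 occupied bins")
    idx = _first_peak_index(rd, prominence)
    return None if idx is None else float(rd.bin_centers[idx])


def _first_minimum_after_peak(rd: RadialDistribution, prominence: float = 0.1):
    """Bin-center s of the first local minimum of g after the first peak, or None."""
    g = np.asarray(rd.g, dtype=float)
    start = _first_peak_index(rd, prominence)
    if start is None:
        return None
    minima, _ = find_peaks(-g[start:])
    if minima.size == 0:
        return None
    return float(rd.bin_centers[start + minima[0]])


def _ensemble_g(N: int, x_min: float, replicates: int, seed: int) -> tuple[RadialDistribution, list]:
    packs = pack_ensemble(PackingConfig(N=N, x_min=x_min, seed=seed), replicates)
    return ensemble_radial_distribution(packs), packs


def critical_xmin(
    N: int,
    xmin_grid,
    replicates: int = 10,
    seed: int = 0,
    prominence: float = 0.1,
) -> float:
    """Smallest grid x_min whose ensemble-averaged g(s) has a first peak.

    Raises :class:`BoundaryUndefinedError` if no grid point develops a
    peak (e.g. a grid confined to the gas regime).
    """
    xmin_grid = np.sort(np.asarray(xmin_grid, dtype=float))
    for x in xmin_grid:
        rd, _ = _ensemble_g(N, float(x), replicates, seed)
        if detect_first_peak(rd, prominence) is not None:
            return float(x)
    raise BoundaryUndefinedError(
        f"no first peak of g(s) on the x_min grid {xmin_grid} at N={N}"
    )


def coordination_boundary(
    N: int,
    xmin_grid,
    replicates: int = 10,
    seed: int = 0,
    prominence: float = 0.1,
) -> float:
    """Alternative boundary from the coordination number.

    Returns the smallest grid x_min at which the mean coordination number
    — neighbors per particle within the first minimum of g after the
    first peak — is well-defined and >= 1.  This rule is a documented
    best-effort surrogate, validated only by consistency with
    :func:`critical_xmin`.
    """
    xmin_grid = np.sort(np.asarray(xmin_grid, dtype=float))
    for x in xmin_grid:
        rd, packs = _ensemble_g(N, float(x), replicates, seed)
        s_min = _first_minimum_after_peak(rd, prominence)
        if s_min is None:
            continue
        # mean number of particles within geodesic distance s_min of each particle
        coord = []
        for p in packs:
            gram = np.clip(p.coords @ p.coords.T, -1, 1)
            d = p.R * np.arccos(gram)
            np.fill_diagonal(d, np.inf)
            coord.append(np.mean(np.sum(d < s_min, axis=1)))
        if np.mean(coord) >= 1.0:
            return float(x)
    raise BoundaryUndefinedError(
        f"coordination number never well-defined on the x_min grid at N={N}"
    )


def compute_phase_diagram(
    N_values=(20, 50, 100, 200, 400, 800, 1000),
    xmin_values=tuple(np.round(np.arange(0.0, 0.7001, 0.05), 2)),
    replicates: int = 30,
    seed: int = 0,
    prominence: float = 0.1,
) -> PhaseDiagram:
    """Neighbor-order compositions and the gas-liquid boundary over a grid.

    For each (N, x_min) cell the mean composition over ``replicates``
    packings is recorded; for each N the boundary x_c is the smallest
    x_min whose ensemble g has a first peak (nan when undefined on the
    grid).
    """
    N_values = np.asarray(N_values, dtype=int)
    xmin_values = np.sort(np.asarray(xmin_values, dtype=float))
    fracs = np.empty((len(N_values), len(xmin_values), 3))
    x_c = np.full(len(N_values), np.nan)
    for i, n in enumerate(N_values):
        found = False
        for j, x in enumerate(xmin_values):
            rd, packs = _ensemble_g(int(n), float(x), replicates, seed)
            comp = np.mean(
                [neighbor_order_summary(spherical_voronoi(p)).fractions for p in packs], axis=0
            )
            fracs[i, j] = comp
            if not found and detect_first_peak(rd, prominence) is not None:
                x_c[i] = x
                found = True
    return PhaseDiagram(
        N_values=N_values,
        xmin_values=xmin_values,
        fractions=fracs,
        x_c=x_c,
        replicates=replicates,
        seed=seed,
    )


def ternary_map(fractions) -> np.ndarray:
    """Map compositions (f_lt6, f_6, f_gt6) to 2D ternary-plot coordinates.

    Corners: z<6 at (0,0), z=6 at (1,0), z>6 at (1/2, sqrt(3)/2).
    Fractions must be normalized to 1.
    """
    f = np.atleast_2d(np.asarray(fractions, dtype=float))
    if f.shape[-1] != 3:
        raise ValueError("fractions must have 3 components")
    if not np.allclose(f.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError("fractions must sum to 1")
    xy = f @ _TERNARY_CORNERS
    return xy if np.asarray(fractions).ndim > 1 else xy[0]


def classify_phase(N: int, x_min: float, diagram: PhaseDiagram) -> str:
    """"liquid" iff x_min >= x_c(N) (boundary inclusive), else "gas".

    x_c is interpolated linearly in N between grid points with a defined
    boundary; N outside the grid range raises ``ValueError``.
    """
    Ns = diagram.N_values
    if N < Ns.min() or N > Ns.max():
        raise ValueError(f"N={N} outside the diagram range [{Ns.min()}, {Ns.max()}]; refusing to extrapolate")
    defined = ~np.isnan(diagram.x_c)
    if not defined.any():
        raise BoundaryUndefinedError("phase diagram has no defined boundary")
    xc = float(np.interp(N, Ns[defined], diagram.x_c[defined]))
    return "liquid" if x_min >= xc else "gas"


def plot_ternary(diagram: PhaseDiagram, ax=None, overlay=None):
    """Ternary composition diagram of an (N, x_min) grid.

    Grid compositions are drawn colored by x_min with constant-N lines;
    ``overlay`` may be an (n, 3) array of extra compositions (e.g. a
    growth trajectory) drawn as connected red points.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    tri = np.vstack([_TERNARY_CORNERS, _TERNARY_CORNERS[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
    for lbl, (x, y), dy in (("z<6", _TERNARY_CORNERS[0], -0.04), ("z=6", _TERNARY_CORNERS[1], -0.04), ("z>6", _TERNARY_CORNERS[2], 0.03)):
        ax.text(x, y + dy, lbl, ha="center", fontsize=9)
    for i in range(len(diagram.N_values)):
        xy = ternary_map(diagram.fractions[i])
        sc = ax.scatter(
            xy[:, 0], xy[:, 1], c=diagram.xmin_values, cmap="viridis", s=18,
            vmin=diagram.xmin_values.min(), vmax=diagram.xmin_values.max(),
        )
        ax.plot(xy[:, 0], xy[:, 1], color="gray", lw=0.5, alpha=0.5)
    plt.colorbar(sc, ax=ax, label="x_min")
    if overlay is not None:
        oxy = ternary_map(np.asarray(overlay))
        ax.plot(oxy[:, 0], oxy[:, 1], "o-", color="crimson", ms=4, lw=1)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


@dataclass(frozen=True)
class TrajectorySpans:
    per_cell: np.ndarray
    mean: float
    max: float


def trajectory_span(traj) -> TrajectorySpans:
    """Maximum excursion of each trajectory from its starting point.

    Every trajectory is recentred so its first position is the origin of
    a local tangent chart; the span is the largest geodesic distance from
    the start over all frames.  Larger spans indicate faster migration.
    """
    pos = traj.positions
    if pos.shape[0] < 2:
        raise ValueError("trajectory_span needs at least 2 frames")
    start = pos[0]  # (N, 3)
    spans = np.zeros(pos.shape[1])
    for f in range(1, pos.shape[0]):
        d = geodesic_distance(start, pos[f], traj.R)
        spans = np.maximum(spans, d)
    return TrajectorySpans(per_cell=spans, mean=float(spans.mean()), max=float(spans.max()))
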