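import numpy as np
import pytest

from spheropack import (
    PackingConfig,
    SpherePoints,
    ensemble_radial_distribution,
    estimate_xmin,
    neighbor_distances,
    pack_ensemble,
    psi6,
    radial_distribution,
    sample_uniform_sphere,
    simulate_min_distance_packing,
    spherical_voronoi,
)
from spheropack.order_metrics import PairDistanceSet
from spheropack.sphere_geometry import average_occupied_length
from conftest import random_rotation


def ring_configuration(n_ring, alpha=0.0, colat=0.5):
    """A central cell at the north pole with n_ring symmetric neighbors,
    plus a far southern cap of anchors so the tessellation is valid."""
    pts = [np.array([0.0, 0.0, 1.0])]
    for k in range(n_ring):
        phi = 2 * np.pi * k / n_ring + alpha
        pts.append(
            [np.sin(colat) * np.cos(phi), np.sin(colat) * np.sin(phi), np.cos(colat)]
        )
    for k in range(3):  # southern anchors
        phi = 2 * np.pi * k / 3 + 0.3
        pts.append([np.sin(2.6) * np.cos(phi), np.sin(2.6) * np.sin(phi), np.cos(2.6)])
    return SpherePoints(np.array(pts))


class TestNeighborDistances:
    def test_tetrahedron_symmetric(self, tetrahedron):
        tess = spherical_voronoi(tetrahedron)
        d = neighbor_distances(tetrahedron, tess)
        assert len(d.distances) == 6
        np.testing.assert_allclose(d.distances, np.arccos(-1 / 3), atol=1e-12)

    def test_packing_respects_floor(self):
        pts = simulate_min_distance_packing(PackingConfig(N=800, x_min=0.57, seed=0))
        d = neighbor_distances(pts, spherical_voronoi(pts))
        assert d.x.min() >= 0.57 - 1e-12

    def test_uniform_has_close_pairs(self):
        pts = sample_uniform_sphere(800, seed=2)
        d = neighbor_distances(pts, spherical_voronoi(pts))
        assert d.x.min() < 0.2

    def test_each_pair_once(self, uniform_100):
        tess = spherical_voronoi(uniform_100)
        d = neighbor_distances(uniform_100, tess)
        assert len(d.distances) == int(tess.z.sum()) // 2


class TestEstimateXmin:
    def test_constant_values(self):
        est = estimate_xmin(PairDistanceSet(np.full(3, 0.4), np.full(3, 0.4), 1.0))
        assert est.x_min == pytest.approx(0.4)
        assert est.sd == pytest.approx(0.0, abs=1e-15)

    def test_hand_computation(self):
        x = np.array([0.5, 0.6, 0.7])
        est = estimate_xmin(PairDistanceSet(x, x, 1.0))
        assert est.x_min == pytest.approx(0.6 - 3 * 0.1)

    def test_sample_sd_convention(self):
        x = np.array([1.0, 2.0])
        est = estimate_xmin(PairDistanceSet(x, x, 1.0))
        assert est.sd == pytest.approx(np.std(x, ddof=1))

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            estimate_xmin(PairDistanceSet(np.array([1.0]), np.array([1.0]), 1.0))


class TestPsi6:
    @pytest.mark.parametrize("alpha", [0.0, 0.37, 1.2])
    def test_perfect_hexagon(self, alpha):
        pts = ring_configuration(6, alpha=alpha)
        res = psi6(pts, spherical_voronoi(pts))
        assert res.per_cell[0] == pytest.approx(1.0, abs=1e-9)

    def test_pentagon_vanishes(self):
        # geometric series: sum of exp(i 6 * 2pi k/5) over k = 0..4 is 0
        pts = ring_configuration(5)
        res = psi6(pts, spherical_voronoi(pts))
        assert res.per_cell[0] == pytest.approx(0.0, abs=1e-9)

    def test_magnitudes_bounded(self, uniform_100):
        res = psi6(uniform_100, spherical_voronoi(uniform_100))
        assert np.all(res.per_cell >= 0) and np.all(res.per_cell <= 1 + 1e-12)
        assert res.mean == pytest.approx(res.per_cell.mean())

    def test_rotation_invariance(self, uniform_100):
        rot = random_rotation(21)
        rotated = SpherePoints(uniform_100.coords @ rot.T)
        a = psi6(uniform_100, spherical_voronoi(uniform_100))
        b = psi6(rotated, spherical_voronoi(rotated))
        np.testing.assert_allclose(a.per_cell, b.per_cell, atol=1e-9)

    def test_uniform_baseline_flat_in_N(self):
        # the random-particle baseline does not order as N grows
        means = {}
        for N in (100, 300, 1000):
            vals = []
            for seed in range(5):
                p = sample_uniform_sphere(N, seed=seed)
                vals.append(psi6(p, spherical_voronoi(p)).mean)
            means[N] = (np.mean(vals), np.std(vals, ddof=1))
        spread = max(m for m, _ in means.values()) - min(m for m, _ in means.values())
        assert spread < 3 * max(s for _, s in means.values())


class TestRadialDistribution:
    def test_counts_conserved(self, uniform_100):
        rd = radial_distribution(uniform_100)
        assert rd.counts.sum() == 100 * 99 // 2

    def test_uniform_is_ideal_gas(self):
        pts = sample_uniform_sphere(5000, seed=6)
        rd = radial_distribution(pts, bin_width=0.05)
        mid = (rd.bin_centers >= 0.2) & (rd.bin_centers <= 3.0)
        assert np.abs(rd.g[mid] - 1).max() < 0.1

    def test_packing_exclusion_zone(self):
        ens = pack_ensemble(PackingConfig(N=800, x_min=0.7, seed=3), 5)
        rd = ensemble_radial_distribution(ens)
        L = average_occupied_length(800, 1.0)
        assert np.all(rd.g[rd.bin_edges[1:] <= 0.7 * L] == 0)
        # short-range structure: some bin just above contact exceeds 1
        near = (rd.bin_centers > 0.7 * L) & (rd.bin_centers < 1.5 * L)
        assert rd.g[near].max() > 1.1

    def test_two_antipodal_points(self):
        pts = SpherePoints(np.array([[0.0, 0, 1], [0.0, 0, -1]]))
        rd = radial_distribution(pts, bin_width=0.5)
        occupied = np.flatnonzero(rd.counts)
        assert len(occupied) == 1
        b = occupied[0]
        lo, hi = rd.bin_edges[b], min(rd.bin_edges[b + 1], np.pi)
        expected = 1 * 0.5 * (np.cos(lo) - np.cos(hi))
        assert rd.g[b] == pytest.approx(1 / expected)

    def test_invalid_bin_width(self, uniform_100):
        with pytest.raises(ValueError):
            radial_distribution(uniform_100, bin_width=-0.1)

    def test_ensemble_requires_matching_sizes(self):
        a = sample_uniform_sphere(50, seed=0)
        b = sample_uniform_sphere(60, seed=0)
        with pytest.raises(ValueError):
            ensemble_radial_distribution([a, b])
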