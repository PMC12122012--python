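import numpy as np
import pytest

from spheropack import (
    PackingConfig,
    classify_phase,
    compute_phase_diagram,
    coordination_boundary,
    critical_xmin,
    detect_first_peak,
    generate_alveolosphere,
    generate_trajectories,
    ternary_map,
    trajectory_span,
)
from spheropack.order_metrics import RadialDistribution
from spheropack.phase_analysis import BoundaryUndefinedError, PhaseDiagram


def make_rd(g, N=800, R=1.0, n_replicates=30):
    """A radial distribution with prescribed g and counts consistent with it."""
    edges = np.linspace(0, np.pi, len(g) + 1)
    n_pairs = N * (N - 1) / 2
    expected = n_pairs * np.diff(0.5 * (1 - np.cos(edges)))
    return RadialDistribution(
        bin_edges=edges,
        g=np.asarray(g, float),
        counts=np.asarray(g) * expected,
        N=N,
        R=R,
        n_replicates=n_replicates,
    )


class TestDetectFirstPeak:
    def test_flat_gas_has_no_peak(self):
        assert detect_first_peak(make_rd(np.ones(40))) is None

    def test_constructed_bump_found(self):
        g = np.ones(40)
        g[12] = 1.5
        rd = make_rd(g)
        assert detect_first_peak(rd) == pytest.approx(rd.bin_centers[12])

    def test_first_of_two_peaks(self):
        g = np.ones(40)
        g[10] = 1.4
        g[25] = 1.8
        rd = make_rd(g)
        assert detect_first_peak(rd) == pytest.approx(rd.bin_centers[10])

    def test_subthreshold_bump_ignored(self):
        g = np.ones(40)
        g[12] = 1.05  # below the 0.1 prominence requirement
        assert detect_first_peak(make_rd(g)) is None

    def test_requires_occupied_bins(self):
        rd = make_rd(np.ones(5))
        with pytest.raises(ValueError):
            detect_first_peak(rd)


class TestCriticalXmin:
    def test_liquid_boundary_inside_range(self):
        xc = critical_xmin(800, np.round(np.arange(0, 0.71, 0.1), 2), replicates=5, seed=1)
        assert 0 < xc < 0.7

    def test_gas_only_grid_undefined(self):
        with pytest.raises(BoundaryUndefinedError):
            critical_xmin(200, [0.0], replicates=5, seed=1)

    def test_coordination_agrees_within_two_steps(self):
        grid = np.round(np.arange(0, 0.71, 0.1), 2)
        xc = critical_xmin(400, grid, replicates=5, seed=2)
        xc_coord = coordination_boundary(400, grid, replicates=5, seed=2)
        assert abs(xc - xc_coord) <= 0.2 + 1e-12

    def test_coordination_gas_undefined(self):
        with pytest.raises(BoundaryUndefinedError):
            coordination_boundary(200, [0.0], replicates=5, seed=1)


class TestTernaryMap:
    def test_vertices(self):
        np.testing.assert_allclose(ternary_map((1, 0, 0)), [0, 0], atol=1e-15)
        np.testing.assert_allclose(ternary_map((0, 1, 0)), [1, 0], atol=1e-15)
        np.testing.assert_allclose(ternary_map((0, 0, 1)), [0.5, np.sqrt(3) / 2], atol=1e-15)

    def test_centroid(self):
        xy = ternary_map((1 / 3, 1 / 3, 1 / 3))
        np.testing.assert_allclose(xy, [0.5, np.sqrt(3) / 6], atol=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            ternary_map((0.5, 0.2, 0.2))

    def test_batch(self):
        xy = ternary_map(np.array([[1, 0, 0], [0, 1, 0]]))
        assert xy.shape == (2, 2)


class TestClassifyPhase:
    @pytest.fixture()
    def diagram(self):
        return PhaseDiagram(
            N_values=np.array([100, 400, 800]),
            xmin_values=np.array([0.0, 0.2, 0.4, 0.6]),
            fractions=np.full((3, 4, 3), 1 / 3),
            x_c=np.array([0.6, 0.5, 0.4]),
            replicates=10,
            seed=0,
        )

    def test_zero_xmin_is_gas(self, diagram):
        for N in (100, 400, 800):
            assert classify_phase(N, 0.0, diagram) == "gas"

    def test_boundary_inclusive(self, diagram):
        assert classify_phase(400, 0.5, diagram) == "liquid"

    def test_monotone_in_xmin(self, diagram):
        phases = [classify_phase(400, x, diagram) for x in np.linspace(0, 0.7, 15)]
        assert "".join("L" if p == "liquid" else "G" for p in phases).count("GL") <= 1
        assert "LG" not in "".join("L" if p == "liquid" else "G" for p in phases)

    def test_interpolation_between_grid_N(self, diagram):
        # x_c(250) interpolates between 0.6 and 0.5
        assert classify_phase(250, 0.58, diagram) == "liquid"
        assert classify_phase(250, 0.5, diagram) == "gas"

    def test_refuses_extrapolation(self, diagram):
        with pytest.raises(ValueError):
            classify_phase(50, 0.3, diagram)


class TestPhaseDiagram:
    def test_small_grid_structure(self):
        diag = compute_phase_diagram(
            N_values=(50, 200), xmin_values=(0.0, 0.3, 0.6), replicates=4, seed=3
        )
        assert diag.fractions.shape == (2, 3, 3)
        np.testing.assert_allclose(diag.fractions.sum(axis=2), 1.0, atol=1e-12)
        # mean f_6 non-decreasing in x_min at each N
        f6 = diag.fractions[:, :, 1]
        assert np.all(np.diff(f6, axis=1) >= -0.02)


class TestTrajectorySpan:
    def test_stationary_zero(self):
        s = generate_alveolosphere(N=30, seed=0)
        traj = generate_trajectories(s, step_scale=0.0, frames=5, seed=1)
        res = trajectory_span(traj)
        assert res.max == pytest.approx(0.0, abs=1e-12)

    def test_great_circle_walk(self):
        # one cell stepping distance d along a great circle for k steps
        import dataclasses

        from spheropack.synthetic_alveolosphere import TrajectorySet

        d, k = 0.1, 4
        angles = np.arange(k + 1) * d
        pos = np.stack(
            [np.stack([np.sin(a) * np.ones(1), np.zeros(1), np.cos(a) * np.ones(1)], axis=1) for a in angles]
        )
        traj = TrajectorySet(positions=pos, R=1.0, interval_min=15.0, metadata={})
        res = trajectory_span(traj)
        assert res.max == pytest.approx(k * d, abs=1e-12)

    def test_gas_phase_more_motile(self):
        s = generate_alveolosphere(N=100, dn_ratio_mean=0.4, seed=2)
        fast = trajectory_span(generate_trajectories(s, step_scale=0.04, frames=10, seed=3))
        slow = trajectory_span(generate_trajectories(s, step_scale=0.02, frames=10, seed=3))
        assert fast.mean > slow.mean

    def test_single_frame_rejected(self):
        s = generate_alveolosphere(N=30, seed=0)
        traj = generate_trajectories(s, frames=2, seed=1)
        import dataclasses

        short = dataclasses.replace(traj, positions=traj.positions[:1])
        with pytest.raises(ValueError):
            trajectory_span(short)


class TestTernaryPlot:
    def test_plot_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        from spheropack.phase_analysis import plot_ternary

        diag = PhaseDiagram(
            N_values=np.array([100, 400]),
            xmin_values=np.array([0.0, 0.3, 0.6]),
            fractions=np.full((2, 3, 3), 1 / 3),
            x_c=np.array([0.6, 0.4]),
            replicates=2,
            seed=0,
        )
        ax = plot_ternary(diag, overlay=np.array([[0.6, 0.3, 0.1], [0.2, 0.6, 0.2]]))
        assert ax is not None
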