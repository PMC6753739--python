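"""Geometry unit tests: blue-noise sampling, Lloyd relaxation, skeleton."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import HalfspaceIntersection, cKDTree
from scipy.spatial.distance import pdist

from vorolung.cvt_geometry import (
    BranchNetwork,
    PhantomSpec,
    PointSet,
    assign_radii,
    build_voronoi_edges,
    cvt_energy,
    lloyd_relax,
    poisson_disk_radius,
    sample_poisson_disk,
)

# ---------------------------------------------------------------------------
# Poisson-disk sampling


def test_poisson_single_point_inside_cube():
    spec = PhantomSpec(n_points=1, seed=0)
    pts = sample_poisson_disk(spec)
    assert len(pts) == 1
    assert np.all(pts.points > 0) and np.all(pts.points < spec.cube_edge)


def test_poisson_minimum_spacing_exhaustive():
    """Every pairwise distance respects the exclusion radius."""
    spec = PhantomSpec(n_points=100, seed=7)
    pts = sample_poisson_disk(spec)
    assert len(pts) == 100
    assert pdist(pts.points).min() >= poisson_disk_radius(spec)


def test_poisson_deterministic_for_seed():
    spec = PhantomSpec(n_points=64, seed=42)
    a = sample_poisson_disk(spec)
    b = sample_poisson_disk(spec)
    np.testing.assert_array_equal(a.points, b.points)


def test_poisson_unsatisfiable_spacing_raises(monkeypatch):
    """An infeasible exclusion radius fails loudly, not by silent undershoot."""
    monkeypatch.setattr(
        "vorolung.cvt_geometry.poisson_disk_radius", lambda spec: 3.0
    )
    with pytest.raises(RuntimeError, match="Poisson-disk"):
        sample_poisson_disk(PhantomSpec(n_points=50, seed=0), max_attempts_per_point=50)


# ---------------------------------------------------------------------------
# Lloyd relaxation


def test_lloyd_single_point_converges_to_cube_center():
    ps = PointSet(points=np.array([[0.5, 3.1, 1.0]]), seed=5, cube_edge=4.0)
    out = lloyd_relax(ps, iterations=5)
    np.testing.assert_allclose(out.points[0], [2.0, 2.0, 2.0], atol=0.03)


def test_lloyd_two_points_converge_to_half_cube_centroids():
    """Two generators split the cube in half; centroids sit at 1/4 and 3/4."""
    ps = PointSet(points=np.array([[2.0, 2.0, 1.2], [2.0, 2.0, 2.9]]), seed=5, cube_edge=4.0)
    out = lloyd_relax(ps, iterations=40)
    z = np.sort(out.points[:, 2])
    np.testing.assert_allclose(z, [1.0, 3.0], atol=0.05)
    np.testing.assert_allclose(out.points[:, :2], 2.0, atol=0.05)


def test_lloyd_energy_monotone_nonincreasing(rng):
    pts = PointSet(points=rng.uniform(0.3, 3.7, (50, 3)), seed=11, cube_edge=4.0)
    out = lloyd_relax(pts, iterations=20, tolerance=0.0)
    trace = np.array(out.energy_trace)
    assert len(trace) == 20
    assert np.all(np.diff(trace) <= 1e-12)


def test_lloyd_energy_matches_dense_monte_carlo_oracle(rng):
    """The traced energy equals an independent dense-sampling estimate."""
    pts = PointSet(points=rng.uniform(0.3, 3.7, (20, 3)), seed=2, cube_edge=4.0)
    out = lloyd_relax(pts, iterations=3, tolerance=0.0)
    oracle_rng = np.random.default_rng(999)
    samples = oracle_rng.uniform(0, 4.0, (400_000, 3))
    oracle = cvt_energy(out.points, samples, 4.0**3)
    assert abs(oracle - out.energy_trace[-1]) / oracle < 0.02


def test_lloyd_coincident_points_raise():
    ps = PointSet(points=np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]), seed=0, cube_edge=4.0)
    with pytest.raises(ValueError, match="coincident"):
        lloyd_relax(ps)


# ---------------------------------------------------------------------------
# Voronoi edge skeleton


def _halfspace_voronoi_edges(points: np.ndarray, edge: float):
    """Brute-force Voronoi skeleton: per-cell bisector half-space intersection.

    Independent of scipy.spatial.Voronoi — each cell is the intersection
    of pairwise bisector half-spaces with the cube, its polytope edges are
    vertex pairs sharing two tight facets.
    """
    n = len(points)
    segments = []
    for i in range(n):
        hs = []
        for j in range(n):
            if j == i:
                continue
            nrm = 2.0 * (points[j] - points[i])
            off = float(points[i] @ points[i] - points[j] @ points[j])
            hs.append([*nrm, off])  # nrm . x + off <= 0
        for ax in range(3):
            row = [0.0, 0.0, 0.0, 0.0]
            row[ax] = -1.0
            hs.append(list(row))  # -x_ax <= 0
            row = [0.0, 0.0, 0.0, -edge]
            row[ax] = 1.0
            hs.append(list(row))  # x_ax <= edge
        A = np.array(hs)
        hsi = HalfspaceIntersection(A, points[i].copy())
        verts = hsi.intersections
        # dedupe numerically identical vertices
        uniq: list[np.ndarray] = []
        for v in verts:
            if not any(np.linalg.norm(v - u) < 1e-9 for u in uniq):
                uniq.append(v)
        tight = [
            set(np.nonzero(np.abs(A[:, :3] @ v + A[:, 3]) < 1e-8)[0]) for v in uniq
        ]
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                if len(tight[a] & tight[b]) >= 2:
                    segments.append((uniq[a], uniq[b]))
    return segments


@pytest.mark.parametrize("n_points", [5, 8])
def test_voronoi_skeleton_matches_halfspace_oracle(n_points):
    rng = np.random.default_rng(100 + n_points)
    pts = PointSet(points=rng.uniform(0.8, 3.2, (n_points, 3)), seed=1, cube_edge=4.0)
    spec = PhantomSpec(n_points=n_points, seed=1)
    net = build_voronoi_edges(pts, spec)

    oracle = _halfspace_voronoi_edges(pts.points, 4.0)
    tree = cKDTree(net.nodes)
    impl_edges = {tuple(sorted(e)) for e in net.edges.tolist()}
    oracle_edges = set()
    for a, b in oracle:
        (da, ia), (db, ib) = tree.query(a), tree.query(b)
        assert da < 1e-9 and db < 1e-9, "oracle vertex missing from implementation"
        if ia != ib:
            oracle_edges.add(tuple(sorted((int(ia), int(ib)))))
    assert oracle_edges == impl_edges


def test_voronoi_edges_clipped_to_cube(small_network):
    spec, net = small_network
    assert net.nodes.min() >= 0.0
    assert net.nodes.max() <= spec.cube_edge


def test_voronoi_degenerate_input_raises():
    # coincident generating points give degenerate (empty) cells
    pts = np.full((6, 3), 2.0)
    pts[:3, 0] = 1.0
    ps = PointSet(points=pts, seed=0, cube_edge=4.0)
    with pytest.raises(ValueError, match="coincident|degenerate"):
        build_voronoi_edges(ps, PhantomSpec(n_points=6, seed=0))


def test_cvt_total_edge_length_concentrates_across_seeds():
    """CVT skeleton length at fixed n is a tight geometric invariant."""
    lengths = []
    for seed in range(10):
        spec = PhantomSpec(n_points=1000, seed=seed)
        pts = lloyd_relax(sample_poisson_disk(spec), iterations=12)
        net = build_voronoi_edges(pts, spec)
        lengths.append(net.total_edge_length())
    lengths = np.array(lengths)
    assert np.all(np.abs(lengths - lengths.mean()) / lengths.mean() < 0.10)


# ---------------------------------------------------------------------------
# radii


def test_assign_radii_single_edge_bounds():
    net = BranchNetwork(
        nodes=np.array([[1.0, 1, 1], [3.0, 3, 3]]),
        edges=np.array([[0, 1]]),
        edge_radius=np.zeros(1),
        node_radius=np.zeros(2),
        cube_edge=4.0,
    )
    spec = PhantomSpec(n_points=5, seed=0)
    out = assign_radii(net, spec, seed=0)
    assert 0.2 <= out.edge_radius[0] <= 0.4
    assert np.all(out.node_radius >= out.edge_radius[0] - 1e-12)


def test_assign_radii_uniform_mean_and_joint_cap(small_network):
    spec, net = small_network
    # uniform on [0.2, 0.4] mm: mean 0.3, sd 0.2/sqrt(12)
    se = (0.2 / np.sqrt(12)) / np.sqrt(net.n_edges)
    assert abs(net.edge_radius.mean() - 0.3) < 3 * se
    assert np.all(net.node_radius <= spec.joint_diameter_max / 2 + 1e-12)
    assert np.all(net.node_radius <= 0.8 + 1e-12)  # <= 1.6 mm diameter


def test_full_geometry_pipeline_reproducible():
    spec = PhantomSpec(n_points=150, seed=9)

    def run():
        pts = lloyd_relax(sample_poisson_disk(spec), iterations=8)
        net = build_voronoi_edges(pts, spec)
        return assign_radii(net, spec, seed=9)

    a, b = run(), run()
    np.testing.assert_array_equal(a.nodes, b.nodes)
    np.testing.assert_array_equal(a.edges, b.edges)
    np.testing.assert_array_equal(a.edge_radius, b.edge_radius)
    np.testing.assert_array_equal(a.node_radius, b.node_radius)
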