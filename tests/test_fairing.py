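import numpy as np
import pytest

from sparsesurf.contours import PlanarContour, SparseContourSet
from sparsesurf.fairing import (
    FairingParams,
    build_tube,
    graph_laplacian,
    reconstruct,
    solve_bilaplacian,
)


def ring(z, r=5.0, n=8, cx=0.0, cy=0.0):
    theta = 2 * np.pi * np.arange(n) / n
    return PlanarContour(z, np.column_stack(
        [cx + r * np.cos(theta), cy + r * np.sin(theta), np.full(n, float(z))]))


def stack(zs, rs=None, n=8):
    rs = rs if rs is not None else [5.0] * len(zs)
    return SparseContourSet([ring(z, r, n) for z, r in zip(zs, rs)])


class TestBuildTube:
    def test_vertex_and_constraint_counts_small(self):
        cset = stack([0.0, 2.0], n=4)
        tube = build_tube(cset, FairingParams(n_intermediate=1, n_points=4))
        assert tube.n_vertices == 3 * 4 + 2 == 14
        assert tube.constrained.sum() == 8

    def test_vertex_count_large(self):
        cset = stack(np.linspace(0, 27, 10), n=64)
        tube = build_tube(cset, FairingParams(n_intermediate=2, n_points=64))
        # 10 known + 2 x 9 intermediate rings = 28 rings, plus 2 apexes
        assert tube.n_vertices == 28 * 64 + 2 == 1794

    @pytest.mark.parametrize("n_int,n_pts", [(1, 4), (2, 8), (3, 16)])
    def test_closed_genus_zero_surface(self, n_int, n_pts):
        cset = stack([0.0, 3.0, 6.0], n=n_pts)
        tube = build_tube(cset, FairingParams(n_intermediate=n_int, n_points=n_pts))
        assert tube.to_trimesh().euler_number == 2

    def test_unequal_point_counts_rejected(self):
        cset = SparseContourSet([ring(0.0, n=8), ring(2.0, n=12)])
        with pytest.raises(ValueError, match="not prepared"):
            build_tube(cset, FairingParams())


class TestGraphLaplacian:
    @pytest.fixture()
    def tube(self):
        return build_tube(stack([0.0, 2.0, 4.0], n=8),
                          FairingParams(n_intermediate=1, n_points=8))

    def test_rows_sum_to_zero_and_unit_diagonal(self, tube):
        L = graph_laplacian(tube)
        np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0, atol=1e-14)
        np.testing.assert_allclose(L.diagonal(), 1.0)

    def test_interior_vertex_has_four_quarter_weights(self, tube):
        L = graph_laplacian(tube).toarray()
        row = L[tube.n_points + 1]  # a vertex on an interior ring
        off = row[row != 0]
        assert sorted(off) == pytest.approx([-0.25] * 4 + [1.0])

    def test_apex_weights_are_one_over_p(self, tube):
        L = graph_laplacian(tube).toarray()
        apex = tube.apex_indices[0]
        off = np.delete(L[apex], apex)
        assert np.count_nonzero(off) == tube.n_points
        np.testing.assert_allclose(off[off != 0], -1.0 / tube.n_points)

    def test_annihilates_constant_field(self, tube):
        L = graph_laplacian(tube)
        c = np.full(tube.n_vertices, 3.7)
        np.testing.assert_allclose(L @ c, 0, atol=1e-12)


def _dense_oracle_solve(tube):
    """Independent dense solve: rebuild L from the ring lattice by hand."""
    R, p = tube.n_rings, tube.n_points
    nv = R * p + 2
    A = np.zeros((nv, nv))
    for i in range(R):
        for j in range(p):
            v = i * p + j
            A[v, i * p + (j + 1) % p] = A[i * p + (j + 1) % p, v] = 1
            if i + 1 < R:
                A[v, (i + 1) * p + j] = A[(i + 1) * p + j, v] = 1
    for j in range(p):
        A[R * p, j] = A[j, R * p] = 1
        A[R * p + 1, (R - 1) * p + j] = A[(R - 1) * p + j, R * p + 1] = 1
    L = np.eye(nv) - A / A.sum(axis=1, keepdims=True)
    B = L @ L
    free = ~tube.constrained
    x = tube.vertices.copy()
    x[free] = np.linalg.solve(
        B[np.ix_(free, free)], -B[np.ix_(free, tube.constrained)] @ x[tube.constrained]
    )
    return x


class TestSolveBilaplacian:
    def test_all_constrained_is_identity(self):
        tube = build_tube(stack([0.0, 2.0], n=6),
                          FairingParams(n_intermediate=1, n_points=6))
        tube.constrained[:] = True
        out = solve_bilaplacian(tube)
        np.testing.assert_array_equal(out.vertices, tube.vertices)

    def test_constrained_vertices_reproduced_verbatim(self):
        cset = stack([0.0, 2.5, 5.0, 7.5], rs=[3.0, 5.0, 5.5, 2.0], n=16)
        tube = build_tube(cset, FairingParams(n_intermediate=2, n_points=16))
        out = solve_bilaplacian(tube)
        np.testing.assert_array_equal(
            out.vertices[tube.constrained], tube.vertices[tube.constrained]
        )

    def test_bilaplacian_residual_below_tolerance(self):
        cset = stack([0.0, 2.0, 4.0, 6.0], rs=[3.0, 6.0, 4.0, 2.5], n=24)
        tube = build_tube(cset, FairingParams(n_intermediate=3, n_points=24))
        out = solve_bilaplacian(tube)
        L = graph_laplacian(out)
        resid = np.abs((L @ (L @ out.vertices)))[~out.constrained].max()
        assert resid <= 1e-8 * max(1.0, np.abs(out.vertices).max())

    def test_matches_dense_oracle_on_tiny_mesh(self):
        cset = stack([0.0, 2.0, 4.0], rs=[2.0, 4.0, 1.5], n=4)
        tube = build_tube(cset, FairingParams(n_intermediate=1, n_points=4))
        assert tube.n_vertices <= 40
        out = solve_bilaplacian(tube)
        oracle = _dense_oracle_solve(tube)
        np.testing.assert_allclose(out.vertices, oracle, atol=1e-10)

    def test_rigid_motion_equivariance(self, rng):
        cset = stack([0.0, 2.0, 4.0, 6.0], rs=[3.0, 5.0, 4.5, 2.0], n=16)
        tube = build_tube(cset, FairingParams(n_intermediate=2, n_points=16))
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t = rng.uniform(-20, 20, 3)
        moved = tube.copy()
        moved.vertices = tube.vertices @ Q.T + t
        a = solve_bilaplacian(moved).vertices
        b = solve_bilaplacian(tube).vertices @ Q.T + t
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_cylinder_symmetry(self):
        """Equal constrained circles: free rings stay circles on the axis,
        with plane positions monotone along the tube."""
        cset = stack([0.0, 4.0, 8.0], rs=[5.0, 5.0, 5.0], n=32)
        tube = build_tube(cset, FairingParams(n_intermediate=3, n_points=32))
        out = solve_bilaplacian(tube)
        z_prev = -np.inf
        for i in range(out.n_rings):
            r_ring = out.ring(i)
            radii = np.linalg.norm(r_ring[:, :2] - r_ring[:, :2].mean(axis=0), axis=1)
            np.testing.assert_allclose(radii, radii[0], atol=1e-9)
            np.testing.assert_allclose(r_ring[:, :2].mean(axis=0), 0, atol=1e-9)
            z = r_ring[:, 2].mean()
            assert z > z_prev
            z_prev = z

    def test_solution_minimizes_membrane_energy_when_symmetric(self, rng):
        """With p = 4 every vertex has degree 4, L is symmetric, and the
        bi-Laplacian solution is the exact minimizer of ||L x||^2 among
        configurations agreeing on the constrained vertices."""
        cset = stack([0.0, 2.0, 4.0], rs=[2.0, 5.0, 3.0], n=4)
        tube = build_tube(cset, FairingParams(n_intermediate=2, n_points=4))
        out = solve_bilaplacian(tube)
        L = graph_laplacian(out).toarray()
        assert np.allclose(L, L.T)
        base = np.sum((L @ out.vertices) ** 2)
        free = ~out.constrained
        for _ in range(20):
            pert = out.vertices.copy()
            pert[free] += rng.standard_normal((free.sum(), 3)) * 0.1
            assert np.sum((L @ pert) ** 2) >= base - 1e-12

    def test_nonfinite_coordinates_rejected(self):
        tube = build_tube(stack([0.0, 2.0], n=6),
                          FairingParams(n_intermediate=1, n_points=6))
        tube.vertices[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            solve_bilaplacian(tube)


class TestReconstruct:
    def test_deterministic_bitwise(self):
        cset = stack([0.0, 3.0, 6.0, 9.0], rs=[3.0, 5.0, 4.0, 2.0], n=32)
        a = reconstruct(cset, FairingParams(n_points=32))
        b = reconstruct(cset, FairingParams(n_points=32))
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_known_contours_appear_verbatim(self):
        cset = stack([0.0, 3.0, 6.0], rs=[4.0, 5.0, 3.0], n=16)
        prepared_pts = [c.points for c in cset.contours]
        mesh = reconstruct(cset, FairingParams(n_points=16))
        vset = {tuple(v) for v in np.round(mesh.vertices, 12)}
        for pts in prepared_pts:
            for p in np.round(pts, 12):
                assert tuple(p) in vset

    def test_watertight_positive_volume(self, ellipsoid_mask):
        from sparsesurf.contours import extract_sparse_contours, mask_to_mesh

        cset = extract_sparse_contours(mask_to_mesh(ellipsoid_mask), 8)
        mesh = reconstruct(cset)
        assert mesh.is_watertight
        assert mesh.volume > 0

    def test_scaling_linearity(self):
        cset = stack([0.0, 3.0, 6.0], rs=[4.0, 5.0, 3.0], n=16)
        alpha = 2.5
        scaled = SparseContourSet(
            [PlanarContour(alpha * c.plane, alpha * c.points) for c in cset.contours]
        )
        params = FairingParams(n_intermediate=2, n_points=16)
        a = reconstruct(scaled, params)
        b = reconstruct(cset, params)
        np.testing.assert_allclose(a.vertices, alpha * b.vertices, atol=1e-9)
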