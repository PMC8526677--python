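"""Mesh construction, P1 finite elements, projector, and SPDE precisions."""

import numpy as np
import pytest
import scipy.sparse as sp
from shapely.geometry import Polygon

from bycatch.geometry import DomainSpec
from bycatch.linalg import NotPositiveDefiniteError, SPDFactor
from bycatch.mesh import (BarrierMesh, FEMOperators, assemble_fem, build_mesh,
                          make_projector)
from bycatch.spde import (FieldParams, marginal_sd, matern_nu1_correlation,
                          precision_barrier, precision_stationary,
                          sample_field)


class TestBuildMesh:
    def test_unit_square_edges_bounded_and_covering(self, unit_square):
        mesh = build_mesh(unit_square, 0.2, extension_km=0.0)
        assert mesh.edge_lengths().max() <= 0.2 + 1e-9
        # union of triangles covers the square
        assert mesh.triangle_areas().sum() == pytest.approx(1.0, abs=1e-9)

    def test_slit_barrier_flags(self, slit_domain, small_mesh):
        cent = small_mesh.centroids()
        import shapely
        inside = shapely.contains_xy(slit_domain.barriers[0],
                                     cent[:, 0], cent[:, 1])
        np.testing.assert_array_equal(small_mesh.barrier_flag, inside)
        assert small_mesh.barrier_flag.any()

    def test_refinement_increases_nodes(self, unit_square):
        coarse = build_mesh(unit_square, 0.2, extension_km=0.0)
        fine = build_mesh(unit_square, 0.1, extension_km=0.0)
        assert fine.n_nodes > coarse.n_nodes

    def test_invalid_edge_args(self, unit_square):
        with pytest.raises(ValueError):
            build_mesh(unit_square, 0.0)
        with pytest.raises(ValueError):
            build_mesh(unit_square, 0.5, 0.2)

    def test_json_round_trip(self, small_mesh, tmp_path):
        path = tmp_path / "mesh.json"
        small_mesh.write_json(path)
        back = BarrierMesh.read_json(path)
        np.testing.assert_allclose(back.nodes, small_mesh.nodes)
        np.testing.assert_array_equal(back.triangles, small_mesh.triangles)
        np.testing.assert_array_equal(back.barrier_flag,
                                      small_mesh.barrier_flag)


class TestFEM:
    def test_single_right_triangle_closed_form(self):
        # unit right triangle with legs 1, 1: the P1 stiffness matrix is
        # [[1, -1/2, -1/2], [-1/2, 1/2, 0], [-1/2, 0, 1/2]]
        mesh = BarrierMesh(nodes=np.array([[0., 0.], [1., 0.], [0., 1.]]),
                           triangles=np.array([[0, 1, 2]]),
                           barrier_flag=np.array([False]),
                           inner_flag=np.array([True]),
                           boundary_extension=0.0)
        fem = assemble_fem(mesh)
        expect = np.array([[1.0, -0.5, -0.5],
                           [-0.5, 0.5, 0.0],
                           [-0.5, 0.0, 0.5]])
        np.testing.assert_allclose(fem.G.toarray(), expect, atol=1e-12)
        np.testing.assert_allclose(fem.c, [1 / 6] * 3, atol=1e-12)

    def test_stiffness_rows_annihilate_constants(self, small_mesh):
        fem = assemble_fem(small_mesh)
        assert np.abs(fem.G @ np.ones(small_mesh.n_nodes)).max() < 1e-10

    def test_mass_conserves_area(self, small_mesh):
        fem = assemble_fem(small_mesh)
        assert fem.c.sum() == pytest.approx(
            small_mesh.triangle_areas().sum(), abs=1e-8)

    def test_zero_area_triangle_rejected(self):
        mesh = BarrierMesh(nodes=np.array([[0., 0.], [1., 0.], [2., 0.]]),
                           triangles=np.array([[0, 1, 2]]),
                           barrier_flag=np.array([False]),
                           inner_flag=np.array([True]),
                           boundary_extension=0.0)
        with pytest.raises(ValueError):
            assemble_fem(mesh)


class TestProjector:
    def test_node_point_is_unit_vector(self, small_mesh):
        proj = make_projector(small_mesh, small_mesh.nodes[[5]])
        row = proj.A[0].toarray().ravel()
        assert row[5] == pytest.approx(1.0)
        assert row.sum() == pytest.approx(1.0)

    def test_centroid_gives_equal_thirds(self):
        mesh = BarrierMesh(nodes=np.array([[0., 0.], [1., 0.], [0., 1.]]),
                           triangles=np.array([[0, 1, 2]]),
                           barrier_flag=np.array([False]),
                           inner_flag=np.array([True]),
                           boundary_extension=0.0)
        proj = make_projector(mesh, np.array([[1 / 3, 1 / 3]]))
        np.testing.assert_allclose(np.sort(proj.A[0].toarray().ravel()),
                                   [1 / 3] * 3, atol=1e-12)

    def test_partition_of_unity(self, small_mesh, rng):
        pts = rng.uniform(1, 7, size=(50, 2))
        proj = make_projector(small_mesh, pts)
        const = proj.A @ np.full(small_mesh.n_nodes, 3.7)
        np.testing.assert_allclose(const[proj.valid], 3.7, atol=1e-9)

    def test_outside_points_flagged(self, small_mesh):
        proj = make_projector(small_mesh, np.array([[100.0, 100.0]]))
        assert not proj.valid[0]
        out = proj.project(np.ones(small_mesh.n_nodes))
        assert np.isnan(out[0])


@pytest.fixture(scope="module")
def fem_and_mesh(slit_domain):
    mesh = build_mesh(slit_domain, 0.7, 1.4, extension_km=1.5)
    return assemble_fem(mesh), mesh


@pytest.fixture(scope="module")
def sample_Q(slit_domain):
    mesh = build_mesh(slit_domain, 1.0, 2.0, extension_km=1.5)
    fem = assemble_fem(mesh)
    return precision_stationary(fem, FieldParams(2.5, 1.0))


class TestStationarySPDE:

    def test_marginal_sd_near_sigma(self, fem_and_mesh):
        fem, mesh = fem_and_mesh
        Q = precision_stationary(fem, FieldParams(2.0, 1.0))
        sd = marginal_sd(Q)
        center = np.argmin(np.linalg.norm(mesh.nodes - [5, 2.5], axis=1))
        assert abs(sd[center] - 1.0) < 0.15

    def test_correlation_matches_matern(self, fem_and_mesh):
        fem, mesh = fem_and_mesh
        Q = precision_stationary(fem, FieldParams(2.0, 1.0))
        S = np.linalg.inv(Q.toarray())
        c = int(np.argmin(np.linalg.norm(mesh.nodes - [4, 2.5], axis=1)))
        j = int(np.argmin(np.linalg.norm(mesh.nodes - [6, 2.5], axis=1)))
        d = np.linalg.norm(mesh.nodes[j] - mesh.nodes[c])
        corr = S[c, j] / np.sqrt(S[c, c] * S[j, j])
        assert abs(corr - matern_nu1_correlation(d, 2.0)) < 0.1

    def test_symmetry(self, fem_and_mesh):
        fem, _ = fem_and_mesh
        Q = precision_stationary(fem, FieldParams(2.0, 1.0))
        assert np.abs((Q - Q.T)).max() < 1e-10

    def test_refinement_consistency_of_marginal_sd(self, slit_domain):
        sds = []
        for h in (1.0, 0.5):
            mesh = build_mesh(slit_domain, h, 2 * h, extension_km=1.5)
            fem = assemble_fem(mesh)
            Q = precision_stationary(fem, FieldParams(2.5, 1.0))
            sd = marginal_sd(Q)
            c = np.argmin(np.linalg.norm(mesh.nodes - [5, 2.5], axis=1))
            sds.append(sd[c])
        assert abs(sds[1] - sds[0]) / sds[0] < 0.05

    def test_positive_params_required(self, fem_and_mesh):
        with pytest.raises(ValueError):
            FieldParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            FieldParams(1.0, 0.0)
        with pytest.raises(ValueError):
            FieldParams(1.0, 1.0, barrier_range_fraction=0.0)


class TestBarrierSPDE:
    @pytest.fixture()
    def setup(self, fem_and_mesh):
        fem, mesh = fem_and_mesh
        return mesh, fem

    def test_reduces_to_stationary_without_barrier(self, unit_square):
        mesh = build_mesh(unit_square, 0.15, extension_km=0.3)
        assert not mesh.barrier_flag.any()
        fem = assemble_fem(mesh)
        p = FieldParams(0.4, 1.0)
        Qs = precision_stationary(fem, p)
        Qb = precision_barrier(fem, mesh, p)
        assert np.abs((Qb - Qs)).max() < 1e-10 * np.abs(Qs).max()

    def test_barrier_cuts_correlation(self, setup):
        mesh, fem = setup
        Q = precision_barrier(fem, mesh, FieldParams(3.0, 1.0, 0.1))
        S = np.linalg.inv(Q.toarray())

        def node(x, y):
            return int(np.argmin(np.linalg.norm(mesh.nodes - [x, y], axis=1)))

        rho = lambda i, j: S[i, j] / np.sqrt(S[i, i] * S[j, j])
        across = rho(node(5, 4), node(5, 6))
        open_w = rho(node(5, 1), node(5, 3))
        assert across < open_w

    def test_monotone_in_barrier_fraction(self, setup):
        mesh, fem = setup

        def across(frac):
            Q = precision_barrier(fem, mesh, FieldParams(3.0, 1.0, frac))
            S = np.linalg.inv(Q.toarray())
            a = int(np.argmin(np.linalg.norm(mesh.nodes - [5, 4], axis=1)))
            b = int(np.argmin(np.linalg.norm(mesh.nodes - [5, 6], axis=1)))
            return S[a, b] / np.sqrt(S[a, a] * S[b, b])

        vals = [across(f) for f in (1.0, 0.5, 0.2, 0.05)]
        assert all(vals[i] >= vals[i + 1] for i in range(len(vals) - 1))

    def test_positive_definite(self, setup):
        mesh, fem = setup
        Q = precision_barrier(fem, mesh, FieldParams(3.0, 1.0, 0.1))
        eigs = np.linalg.eigvalsh(Q.toarray())
        assert eigs.min() > 0


class TestSampling:
    @pytest.fixture()
    def Q(self, sample_Q):
        return sample_Q

    def test_same_seed_identical(self, Q):
        a = sample_field(Q, 10, seed=3)
        b = sample_field(Q, 10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_mean_within_clt_bound(self, Q):
        draws = sample_field(Q, 5000, seed=4)
        sd = marginal_sd(Q)
        bound = 4 * sd / np.sqrt(5000)
        assert (np.abs(draws.mean(axis=0)) < bound).mean() > 0.99

    def test_sample_covariance_matches_inverse(self, Q):
        draws = sample_field(Q, 8000, seed=5)
        S = np.linalg.inv(Q.toarray())
        idx = [3, 20, 40]
        emp = np.cov(draws[:, idx].T)
        ref = S[np.ix_(idx, idx)]
        assert np.abs(emp - ref).max() / np.abs(ref).max() < 0.1

    def test_invalid_draw_count(self, Q):
        with pytest.raises(ValueError):
            sample_field(Q, 0, seed=1)


def test_precision_exports_to_matrix_market(sample_Q, tmp_path):
    from scipy.io import mmread
    from bycatch.spde import export_mtx
    path = tmp_path / "Q.mtx"
    export_mtx(sample_Q, path)
    back = mmread(path)
    assert np.abs((back - sample_Q)).max() < 1e-12


class TestSPDFactor:
    def test_matches_dense(self, rng):
        A = sp.random(40, 40, density=0.2, random_state=7)
        Q = (A @ A.T + sp.identity(40) * 40).tocsc()
        f = SPDFactor(Q)
        dense = Q.toarray()
        assert f.logdet == pytest.approx(np.linalg.slogdet(dense)[1])
        b = rng.standard_normal(40)
        np.testing.assert_allclose(f.solve(b), np.linalg.solve(dense, b),
                                   rtol=1e-8)
        draws = f.sample(np.random.default_rng(0), 20000)
        emp = np.cov(draws[:, :5].T)
        ref = np.linalg.inv(dense)[:5, :5]
        assert np.abs(emp - ref).max() < 5 * np.abs(ref).max() / np.sqrt(20000) * 10

    def test_indefinite_rejected(self):
        Q = sp.diags([1.0, -1.0, 1.0]).tocsc()
        with pytest.raises(NotPositiveDefiniteError):
            SPDFactor(Q, jitter=0.0)
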