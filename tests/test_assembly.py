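import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpmono.assembly import (assemble_mass, assemble_operators,
                             assemble_stiffness, build_nodal_space,
                             evaluation_matrix, nodal_to_hierarchical,
                             rhs_matrix_based, rhs_quadrature)
from hpmono.dof_numbering import DofMap
from hpmono.meshing import build_interval_mesh


def random_poly_2d(rng, degree=4):
    terms = [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]
    coeffs = rng.normal(size=len(terms))

    def f(pts):
        x, y = pts[:, 0], pts[:, 1]
        return sum(c * x ** i * y ** j for c, (i, j) in zip(coeffs, terms))
    return f


@pytest.fixture(scope="module")
def ops(small_square_mesh):
    return assemble_operators(small_square_mesh, 3, 4, np.eye(2))


def test_1d_mass_and_stiffness_closed_forms():
    unit = build_interval_mesh(1.0, 1.0)
    h = 0.37
    seg = build_interval_mesh(h, h)
    M1 = assemble_mass(seg, DofMap(seg, 1)).toarray()
    np.testing.assert_allclose(M1, h / 6 * np.array([[2, 1], [1, 2]]), atol=1e-15)
    M2 = assemble_mass(unit, DofMap(unit, 2)).toarray()
    assert M2[0, 2] == pytest.approx(1 / 12)  # (1-x, bubble)
    A1 = assemble_stiffness(unit, DofMap(unit, 1), 1.0).toarray()
    np.testing.assert_allclose(A1, [[1, -1], [-1, 1]], atol=1e-14)
    A2 = assemble_stiffness(unit, DofMap(unit, 2), 1.0).toarray()
    assert A2[2, 2] == pytest.approx(1 / 3)  # int (1-2x)^2


def test_mass_spd_and_linear_block_measure(ops, small_square_mesh):
    np.linalg.cholesky(ops.M.toarray())  # SPD <=> Cholesky succeeds
    V = small_square_mesh.n_vertices
    assert ops.M[:V, :V].sum() == pytest.approx(1.0, rel=1e-10)  # |Omega|


def test_stiffness_kernel_is_exactly_constants(ops, small_square_mesh):
    c = np.zeros(ops.dofmap.n_dofs)
    c[: small_square_mesh.n_vertices] = 1.0
    Anorm = abs(ops.A).max()
    assert np.abs(ops.A @ c).max() <= 1e-10 * Anorm
    # kernel dimension exactly 1 on a connected mesh
    w = np.linalg.eigvalsh(ops.A.toarray())
    assert (w < 1e-10 * Anorm).sum() == 1
    assert w.min() > -1e-10 * Anorm


def test_stiffness_linearity_in_sigma(small_square_mesh):
    dm = DofMap(small_square_mesh, 2)
    A1 = assemble_stiffness(small_square_mesh, dm, 1.0)
    A3 = assemble_stiffness(small_square_mesh, dm, 3.0)
    assert abs(A3 - 3.0 * A1).max() < 1e-12 * abs(A1).max()


def test_non_spd_sigma_reported_with_location(small_square_mesh):
    dm = DofMap(small_square_mesh, 1)
    bad = lambda pts: np.broadcast_to(np.diag([1.0, -0.5]), (len(pts), 2, 2))
    with pytest.raises(ValueError, match="not SPD"):
        assemble_stiffness(small_square_mesh, dm, bad)


def test_nodal_to_hierarchical_basics(small_square_mesh):
    mesh = small_square_mesh
    dm4 = DofMap(mesh, 4)
    nodal = build_nodal_space(mesh, 4)
    # linear data -> higher-mode coefficients all zero
    vals = 2.0 + 3.0 * nodal.coords[:, 0] - nodal.coords[:, 1]
    c = nodal_to_hierarchical(vals, mesh, dm4, nodal, check=True)
    assert np.abs(c[mesh.n_vertices:]).max() < 1e-10
    v = mesh.vertices
    np.testing.assert_allclose(c[: mesh.n_vertices],
                               2.0 + 3.0 * v[:, 0] - v[:, 1], atol=1e-12)


def test_nodal_roundtrip_1d_bubble():
    mesh = build_interval_mesh(1.0, 1.0)
    dm = DofMap(mesh, 2)
    nodal = build_nodal_space(mesh, 2)
    vals = nodal.coords[:, 0] * (1.0 - nodal.coords[:, 0])
    c = nodal_to_hierarchical(vals, mesh, dm, nodal)
    np.testing.assert_allclose(c, [0.0, 0.0, 1.0], atol=1e-13)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_nodal_roundtrip_polynomials(small_square_mesh, seed):
    """nodal -> hierarchical -> evaluate-at-nodes reproduces any degree-4
    polynomial's nodal values to 1e-10."""
    mesh = small_square_mesh
    rng = np.random.default_rng(seed)
    f = random_poly_2d(rng, 4)
    dm4 = DofMap(mesh, 4)
    nodal = build_nodal_space(mesh, 4)
    vals = f(nodal.coords)
    c = nodal_to_hierarchical(vals, mesh, dm4, nodal, check=True)
    back = evaluation_matrix(mesh, dm4, nodal) @ c
    assert np.abs(back - vals).max() <= 1e-10 * max(1.0, np.abs(vals).max())


def test_matrix_based_rhs_equals_quadrature_oracle(ops, small_square_mesh, rng):
    """Central correctness check of the assembly shortcut: the sparse
    product reproduces direct Gauss-quadrature assembly for 50 random
    polynomial current fields to 1e-11 relative."""
    mesh = small_square_mesh
    for _ in range(50):
        f = random_poly_2d(rng, 4)
        vals = f(ops.nodal.coords)
        coeffs = ops.Tmat @ vals
        got = rhs_matrix_based(ops.Mtilde, coeffs)
        want = rhs_quadrature(mesh, ops.dofmap, ops.nodal, vals)
        assert np.abs(got - want).max() <= 1e-11 * np.abs(want).max()


def test_rhs_constant_current(ops, small_square_mesh):
    c = 7.3
    vals = np.full(ops.nodal.n_nodes, c)
    I = rhs_matrix_based(ops.Mtilde, ops.Tmat @ vals)
    V = small_square_mesh.n_vertices
    assert I[:V].sum() == pytest.approx(c * 1.0, rel=1e-10)  # c |Omega|
    zero = rhs_matrix_based(ops.Mtilde, ops.Tmat @ np.zeros(ops.nodal.n_nodes))
    assert np.abs(zero).max() == 0.0


def test_galerkin_projection_recovers_polynomials(ops, small_square_mesh, rng):
    """Projecting a degree-<=3 function into S_hp via M recovers it."""
    import scipy.sparse.linalg as spla
    mesh = small_square_mesh
    f = random_poly_2d(rng, 3)
    vals = f(ops.nodal.coords)
    rhs = rhs_quadrature(mesh, ops.dofmap, ops.nodal, vals)
    proj = spla.spsolve(ops.M.tocsc(), rhs)
    # the interpolant coefficients represent f exactly; compare pointwise
    got = evaluation_matrix(mesh, ops.dofmap, ops.nodal) @ proj
    assert np.abs(got - vals).max() <= 1e-9 * max(1.0, np.abs(vals).max())


def test_mtilde_rows_match_square_mass(small_square_mesh):
    """Nested numbering: rows of the rectangular mass for shared modes
    coincide with rows of the degree-p_tilde square mass."""
    mesh = small_square_mesh
    ops = assemble_operators(mesh, 2, 4, np.eye(2))
    M4 = assemble_mass(mesh, ops.dofmap_pt)
    emb = ops.dofmap.embed_indices(ops.dofmap_pt)
    import scipy.sparse as sp
    diff = abs(ops.Mtilde - sp.csr_matrix(M4)[emb, :])
    assert diff.max() == 0.0
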