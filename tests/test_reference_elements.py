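import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpmono.reference_elements import (HierarchicalBasis, gauss_lobatto_points_1d,
                                       gauss_rule, hierarchical_basis_interval,
                                       hierarchical_basis_triangle, nodal_points)


def bary_integral(a, b, c):
    """Exact integral of lam1^a lam2^b lam3^c over the reference triangle."""
    return (math.factorial(a) * math.factorial(b) * math.factorial(c)
            / math.factorial(a + b + c + 2))


@pytest.mark.parametrize("p,n1,n2", [(1, 2, 3), (2, 3, 6), (3, 4, 10), (4, 5, 15)])
def test_mode_counts(p, n1, n2):
    assert hierarchical_basis_interval(p).n_modes == n1
    assert hierarchical_basis_triangle(p).n_modes == n2


@pytest.mark.parametrize("dim", [1, 2])
def test_hierarchical_nesting(dim):
    """Degree-p mode list is a prefix of the degree-(p+1) list."""
    for p in range(1, 4):
        lo = HierarchicalBasis(dim, p).modes
        hi = HierarchicalBasis(dim, p + 1).modes
        assert hi[: len(lo)] == lo


def test_interval_cubic_basis_is_the_classic_set():
    """p=3 modes are exactly 1-x, x, x(1-x), x(1-x)(1/2-x)."""
    b = hierarchical_basis_interval(3)
    x = np.linspace(0.0, 1.0, 17)
    expect = [1 - x, x, x * (1 - x), x * (1 - x) * (0.5 - x)]
    vals = b.evaluate(x)
    for row, ref in zip(vals, expect):
        np.testing.assert_allclose(row, ref, atol=1e-14)


def test_partition_of_unity_vertex_modes(rng):
    xs = rng.random(100)
    b1 = hierarchical_basis_interval(4)
    assert np.abs(b1.evaluate(xs)[:2].sum(0) - 1).max() <= 1e-13
    pts = rng.random((300, 2))
    pts = pts[pts.sum(axis=1) < 1][:100]
    b2 = hierarchical_basis_triangle(4)
    assert np.abs(b2.evaluate(pts)[:3].sum(0) - 1).max() <= 1e-13


def test_edge_and_interior_modes_vanish_where_required():
    b = hierarchical_basis_triangle(4)
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    vals = b.evaluate(corners)
    for m, mode in enumerate(b.modes):
        if mode.kind != "vertex":
            assert np.abs(vals[m]).max() < 1e-14
    # interior modes vanish on the whole boundary
    s = np.linspace(0, 1, 13)
    boundary = np.vstack([np.column_stack([s, 0 * s]),
                          np.column_stack([0 * s, s]),
                          np.column_stack([s, 1 - s])])
    vals = b.evaluate(boundary)
    for m, mode in enumerate(b.modes):
        if mode.kind == "interior":
            assert np.abs(vals[m]).max() < 1e-14


def test_quartic_modes_linearly_independent():
    """Gram matrix of the full p=4 triangle basis is nonsingular."""
    b = hierarchical_basis_triangle(4)
    rule = gauss_rule(2, 8)
    V = b.evaluate(rule.points)
    G = (V * rule.weights) @ V.T
    assert np.isfinite(np.linalg.cond(G))
    assert np.linalg.matrix_rank(G, tol=1e-12) == 15
    # 1D quartic bubble vanishes at the endpoints and completes rank 5
    b1 = hierarchical_basis_interval(4)
    assert np.abs(b1.evaluate(np.array([0.0, 1.0]))[4]).max() < 1e-14
    xs = np.linspace(0, 1, 5)
    assert np.linalg.matrix_rank(b1.evaluate(xs)) == 5


def test_edge_trace_matches_1d_mode_up_to_scale():
    """Triangle edge-mode traces reduce to the 1D modes of equal degree."""
    b2 = hierarchical_basis_triangle(4)
    b1 = hierarchical_basis_interval(4)
    s = np.linspace(0.03, 0.97, 24)  # avoids s=1/2, a root of the cubic
    edge_pts = np.column_stack([s, 0 * s])     # edge (v0, v1): lam2 = s
    tr = b2.evaluate(edge_pts)
    ref = b1.evaluate(s)
    for m, mode in enumerate(b2.modes):
        if mode.kind == "edge" and mode.entity == 0:
            d = mode.degree
            ratio = tr[m] / ref[d]  # 1D mode of degree d sits at index d
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)


def test_gauss_lobatto_points():
    np.testing.assert_allclose(gauss_lobatto_points_1d(1), [0.0, 1.0])
    # degree 4: 0, (1 -/+ sqrt(3/7))/2, 1/2, 1 — roots of (1-xi^2) P4'(xi)
    expect = np.array([0.0, (1 - np.sqrt(3 / 7)) / 2, 0.5,
                       (1 + np.sqrt(3 / 7)) / 2, 1.0])
    np.testing.assert_allclose(np.sort(gauss_lobatto_points_1d(4)), expect,
                               atol=1e-12)


@pytest.mark.parametrize("dim,p", [(1, 1), (1, 4), (1, 6), (2, 2), (2, 4), (2, 6)])
def test_nodal_cardinality(dim, p):
    nb = nodal_points(dim, p)
    C = nb.evaluate(nb.points)
    assert np.abs(C - np.eye(nb.n_nodes)).max() <= 1e-10


def test_nodal_counts_and_edge_traces():
    nb = nodal_points(2, 2)
    # degree-2 set: 3 vertices + 3 edge midpoints
    kinds = [c[0] for c in nb.classification]
    assert kinds.count("vertex") == 3 and kinds.count("edge") == 3
    mids = [nb.points[i] for i, c in enumerate(nb.classification)
            if c[0] == "edge"]
    assert sorted(tuple(np.round(m, 12)) for m in mids) == \
        [(0.0, 0.5), (0.5, 0.0), (0.5, 0.5)]
    # degree-6 edge trace equals the 1D Gauss-Lobatto interior points
    nb6 = nodal_points(2, 6)
    e0 = [i for i, c in enumerate(nb6.classification)
          if c[0] == "edge" and c[1] == 0]
    np.testing.assert_allclose(nb6.points[e0][:, 0],
                               gauss_lobatto_points_1d(6)[1:-1], atol=1e-12)
    assert np.abs(nb6.points[e0][:, 1]).max() < 1e-12


def test_quadrature_closed_forms():
    r1 = gauss_rule(1, 3)
    assert abs(r1.weights @ r1.points[:, 0] ** 3 - 0.25) < 1e-14
    r2 = gauss_rule(2, 8)
    assert abs(r2.weights.sum() - 0.5) < 1e-13
    lam1 = 1 - r2.points[:, 0] - r2.points[:, 1]
    lam2 = r2.points[:, 0]
    got = r2.weights @ (lam1 ** 4 * lam2 ** 4)
    assert abs(got - bary_integral(4, 4, 0)) < 1e-15


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4))
def test_quadrature_exactness_property(a, b, c):
    """Every barycentric monomial up to the stated degree integrates to the
    closed form within 1e-12 relative."""
    deg = a + b + c
    rule = gauss_rule(2, max(deg, 1))
    assert (rule.weights > 0).all()
    lam1 = 1 - rule.points[:, 0] - rule.points[:, 1]
    lam2, lam3 = rule.points[:, 0], rule.points[:, 1]
    got = rule.weights @ (lam1 ** a * lam2 ** b * lam3 ** c)
    expect = bary_integral(a, b, c)
    assert abs(got - expect) <= 1e-12 * max(abs(expect), 1e-6)


def test_degree_bounds_rejected():
    with pytest.raises(ValueError):
        hierarchical_basis_interval(5)
    with pytest.raises(ValueError):
        hierarchical_basis_triangle(0)
    with pytest.raises(ValueError):
        nodal_points(2, 7)
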