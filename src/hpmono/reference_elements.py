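"""Reference-element machinery: hierarchical and nodal polynomial bases,
quadrature rules and nodal point sets on the unit interval and the unit
reference triangle.

Two families of bases coexist:

* a *hierarchical* basis of degree ``p`` (1..4) used for the transmembrane
  potential.  The degree-p mode list is a prefix of the degree-(p+1) list,
  so spaces are nested and a degree can be raised without renumbering the
  lower modes.
* a *nodal* (Lagrange) basis of degree ``p_tilde`` (1..6) built on
  Gauss-Lobatto points, used for the cell-state variables and for
  interpolating the transmembrane current before it is pushed back into
  the hierarchical space.

The reference triangle has vertices (0,0), (1,0), (0,1); barycentric
coordinates are lam1 = 1-x-y, lam2 = x, lam3 = y, associated with the
vertices in that order.  Local edges are the sorted local-vertex pairs
(0,1), (1,2), (0,2).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.special import eval_jacobi, roots_jacobi, roots_legendre

__all__ = [
    "Mode",
    "HierarchicalBasis",
    "NodalBasis",
    "QuadratureRule",
    "hierarchical_basis_interval",
    "hierarchical_basis_triangle",
    "nodal_points",
    "gauss_rule",
    "gauss_lobatto_points_1d",
    "LOCAL_EDGES",
]

#: local edges of the reference triangle as sorted local-vertex pairs
LOCAL_EDGES = ((0, 1), (1, 2), (0, 2))

#: gradients of the barycentric coordinates on the reference triangle
_BARY_GRADS = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])

#: interior mode counts per hierarchical degree (2D)
INTERIOR_MODES_2D = {1: 0, 2: 0, 3: 1, 4: 3}


@dataclass(frozen=True)
class Mode:
    """Descriptor of one hierarchical mode.

    kind is "vertex", "edge" or "interior"; entity is the local vertex or
    edge index the mode is attached to (0 for interior modes in 1D);
    degree is the polynomial degree of the mode.  ``odd`` marks modes that
    change sign under reversal of their edge's orientation.
    """

    kind: str
    entity: int
    degree: int
    odd: bool = False


class HierarchicalBasis:
    """Hierarchical modal basis on the reference interval or triangle."""

    def __init__(self, dimension: int, degree: int):
        if not 1 <= degree <= 4:
            raise ValueError(f"hierarchical degree must be in 1..4, got {degree}")
        if dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        self.dimension = dimension
        self.degree = degree
        self.modes = _mode_list(dimension, degree)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Values of all modes at ``points``; shape (n_modes, n_points)."""
        points = np.asarray(points, dtype=float)
        if self.dimension == 1:
            x = points.reshape(-1)
            return np.array([_interval_mode_val(m, x) for m in range(self.n_modes)])
        pts = points.reshape(-1, 2)
        lam = _barycentric(pts)
        return np.array([_triangle_mode_val(self.modes[m], lam) for m in range(self.n_modes)])

    def gradients(self, points: np.ndarray) -> np.ndarray:
        """Gradients of all modes; shape (n_modes, n_points, dim)."""
        points = np.asarray(points, dtype=float)
        if self.dimension == 1:
            x = points.reshape(-1)
            return np.array([_interval_mode_grad(m, x) for m in range(self.n_modes)])[..., None]
        pts = points.reshape(-1, 2)
        lam = _barycentric(pts)
        return np.array([_triangle_mode_grad(self.modes[m], lam) for m in range(self.n_modes)])


def _mode_list(dim: int, degree: int) -> list[Mode]:
    if dim == 1:
        modes = [Mode("vertex", 0, 1), Mode("vertex", 1, 1)]
        for d in range(2, degree + 1):
            modes.append(Mode("interior", 0, d, odd=(d % 2 == 1)))
        return modes
    modes = [Mode("vertex", v, 1) for v in range(3)]
    if degree >= 2:
        modes += [Mode("edge", e, 2) for e in range(3)]
    if degree >= 3:
        modes += [Mode("edge", e, 3, odd=True) for e in range(3)]
        modes += [Mode("interior", 0, 3)]
    if degree >= 4:
        modes += [Mode("edge", e, 4) for e in range(3)]
        modes += [Mode("interior", 0, 4), Mode("interior", 1, 4)]
    return modes


def _barycentric(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.stack([1.0 - x - y, x, y])


# -- interval modes on [0, 1]: 1-x, x, x(1-x), x(1-x)(1/2-x), quartic bubble --

def _interval_mode_val(m: int, x: np.ndarray) -> np.ndarray:
    b2 = x * (1.0 - x)
    if m == 0:
        return 1.0 - x
    if m == 1:
        return x + 0.0 * x
    if m == 2:
        return b2
    if m == 3:
        return b2 * (0.5 - x)
    if m == 4:
        t = 2.0 * x - 1.0
        return b2 * (5.0 * t * t - 1.0) / 4.0
    raise IndexError(m)


def _interval_mode_grad(m: int, x: np.ndarray) -> np.ndarray:
    if m == 0:
        return np.full_like(x, -1.0)
    if m == 1:
        return np.ones_like(x)
    d2 = 1.0 - 2.0 * x
    if m == 2:
        return d2
    if m == 3:
        return d2 * (0.5 - x) - x * (1.0 - x)
    if m == 4:
        t = 2.0 * x - 1.0
        k2 = (5.0 * t * t - 1.0) / 4.0
        return d2 * k2 + x * (1.0 - x) * 5.0 * t
    raise IndexError(m)


def _triangle_mode_val(mode: Mode, lam: np.ndarray) -> np.ndarray:
    if mode.kind == "vertex":
        return lam[mode.entity].copy()
    if mode.kind == "edge":
        a, b = LOCAL_EDGES[mode.entity]
        la, lb = lam[a], lam[b]
        if mode.degree == 2:
            return la * lb
        t = lb - la
        if mode.degree == 3:
            return la * lb * t
        return la * lb * (5.0 * t * t - 1.0) / 4.0
    bub = lam[0] * lam[1] * lam[2]
    if mode.degree == 3:
        return bub
    return bub * lam[mode.entity]


def _triangle_mode_grad(mode: Mode, lam: np.ndarray) -> np.ndarray:
    G = _BARY_GRADS
    n = lam.shape[1]
    if mode.kind == "vertex":
        return np.broadcast_to(G[mode.entity], (n, 2)).copy()
    if mode.kind == "edge":
        a, b = LOCAL_EDGES[mode.entity]
        la, lb = lam[a], lam[b]
        if mode.degree == 2:
            return np.outer(lb, G[a]) + np.outer(la, G[b])
        t = lb - la
        if mode.degree == 3:
            return (np.outer(lb * t, G[a]) + np.outer(la * t, G[b])
                    + np.outer(la * lb, G[b] - G[a]))
        k2 = (5.0 * t * t - 1.0) / 4.0
        return (np.outer(lb * k2, G[a]) + np.outer(la * k2, G[b])
                + np.outer(la * lb * 2.5 * t, G[b] - G[a]))
    l1, l2, l3 = lam
    if mode.degree == 3:
        return np.outer(l2 * l3, G[0]) + np.outer(l1 * l3, G[1]) + np.outer(l1 * l2, G[2])
    k = mode.entity  # extra barycentric factor lam_k
    bub_grad = (np.outer(l2 * l3, G[0]) + np.outer(l1 * l3, G[1])
                + np.outer(l1 * l2, G[2]))
    return bub_grad * lam[k][:, None] + np.outer(l1 * l2 * l3, G[k])


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Points and positive weights on the reference element."""

    dimension: int
    points: np.ndarray  # (nq, dim)
    weights: np.ndarray  # (nq,)
    exactness: int


def gauss_rule(dimension: int, exactness: int) -> QuadratureRule:
    """Quadrature rule on the reference element, exact to ``exactness``.

    1D: Gauss-Legendre on [0,1].  2D: a collapsed (Duffy) tensor rule,
    Gauss-Legendre x Gauss-Jacobi(1,0), which keeps all weights positive at
    any exactness.
    """
    if exactness < 0:
        raise ValueError("exactness must be non-negative")
    n = max(1, (exactness + 2) // 2)  # 2n-1 >= exactness
    xg, wg = roots_legendre(n)
    xg = 0.5 * (xg + 1.0)
    wg = 0.5 * wg
    if dimension == 1:
        return QuadratureRule(1, xg.reshape(-1, 1), wg, 2 * n - 1)
    if dimension != 2:
        raise ValueError("dimension must be 1 or 2")
    xj, wj = roots_jacobi(n, 1.0, 0.0)
    v = 0.5 * (xj + 1.0)
    wv = wj / 4.0
    U, V = np.meshgrid(xg, v, indexing="ij")
    X = U * (1.0 - V)
    Y = V
    W = np.outer(wg, wv)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    return QuadratureRule(2, pts, W.ravel(), 2 * n - 1)


# ---------------------------------------------------------------------------
# nodal (Gauss-Lobatto) point sets and Lagrange bases
# ---------------------------------------------------------------------------

def gauss_lobatto_points_1d(p: int) -> np.ndarray:
    """Gauss-Lobatto points of degree ``p`` mapped to [0, 1], ascending."""
    if p < 1:
        raise ValueError("degree must be >= 1")
    if p == 1:
        return np.array([0.0, 1.0])
    xi, _ = roots_jacobi(p - 1, 1.0, 1.0)  # roots of P'_p on (-1, 1)
    xi = np.concatenate([[-1.0], np.sort(xi), [1.0]])
    return 0.5 * (xi + 1.0)


# warp & blend alpha parameters, indexed by degree (Warburton-style)
_WB_ALPHA = {1: 0.0, 2: 0.0, 3: 1.4152, 4: 0.1001, 5: 0.2751, 6: 0.9800}


def _warp_factor(p: int, r: np.ndarray) -> np.ndarray:
    """1D warp pulling equispaced points to Gauss-Lobatto, on [-1, 1]."""
    gl = 2.0 * gauss_lobatto_points_1d(p) - 1.0
    req = np.linspace(-1.0, 1.0, p + 1)
    # Lagrange interpolation (from equispaced nodes) of the displacement
    V = np.array([np.sqrt(k + 0.5) * eval_jacobi(k, 0.0, 0.0, req) for k in range(p + 1)])
    P = np.array([np.sqrt(k + 0.5) * eval_jacobi(k, 0.0, 0.0, r) for k in range(p + 1)])
    L = np.linalg.solve(V, P)  # (p+1, n): Lagrange cardinal values at r
    warp = L.T @ (gl - req)
    zerof = np.abs(r) < 1.0 - 1e-10
    sf = 1.0 - (np.where(zerof, r, 0.0)) ** 2
    return np.where(zerof, warp / sf, 0.0)


def _warp_blend_triangle(p: int) -> tuple[np.ndarray, list]:
    """Degree-p nodal set on the reference triangle with GL edge traces.

    Returns (points, classification) where classification is a list of
    (kind, entity, rank) tuples in the same canonical ordering used for
    element-local nodal numbering: 3 vertices, then edges (0,1), (1,2),
    (0,2) interior nodes each ordered from first to second vertex, then
    interior nodes.
    """
    idx = []
    for i in range(p, -1, -1):
        for j in range(p - i, -1, -1):
            k = p - i - j
            idx.append((i, j, k))
    idx = np.array(idx, dtype=float)
    lam = idx / p  # columns: lam1, lam2, lam3
    L1, L2, L3 = lam[:, 0], lam[:, 1], lam[:, 2]

    # equilateral coordinates
    x = -L2 + L3
    y = (-L2 - L3 + 2.0 * L1) / np.sqrt(3.0)
    alpha = _WB_ALPHA.get(p, 5.0 / 3.0)
    blend1 = 4.0 * L2 * L3
    blend2 = 4.0 * L1 * L3
    blend3 = 4.0 * L1 * L2
    wf1 = _warp_factor(p, L3 - L2)
    wf2 = _warp_factor(p, L1 - L3)
    wf3 = _warp_factor(p, L2 - L1)
    w1 = blend1 * wf1 * (1.0 + (alpha * L1) ** 2)
    w2 = blend2 * wf2 * (1.0 + (alpha * L2) ** 2)
    w3 = blend3 * wf3 * (1.0 + (alpha * L3) ** 2)
    x = x + 1.0 * w1 + np.cos(2.0 * np.pi / 3.0) * w2 + np.cos(4.0 * np.pi / 3.0) * w3
    y = y + 0.0 * w1 + np.sin(2.0 * np.pi / 3.0) * w2 + np.sin(4.0 * np.pi / 3.0) * w3
    # back to barycentric, then to the reference triangle
    B1 = (np.sqrt(3.0) * y + 1.0) / 3.0
    B2 = (-3.0 * x - np.sqrt(3.0) * y + 2.0) / 6.0
    B3 = (3.0 * x - np.sqrt(3.0) * y + 2.0) / 6.0
    pts = np.column_stack([B2, B3])  # x = lam2, y = lam3

    ii = np.rint(idx).astype(int)
    order, classification = _canonical_node_order(ii, p)
    return pts[order], classification


def _canonical_node_order(ii: np.ndarray, p: int):
    """Canonical ordering of lattice nodes: vertices, edges, interior."""
    n = len(ii)
    tags = []
    for r in range(n):
        i, j, k = (int(v) for v in ii[r])
        nz = int(i > 0) + int(j > 0) + int(k > 0)
        if nz == 1:
            v = 0 if i > 0 else (1 if j > 0 else 2)
            tags.append(("vertex", v, 0, r))
        elif nz == 2:
            if k == 0:  # edge (0,1), order v0 -> v1 means decreasing i
                tags.append(("edge", 0, p - i, r))
            elif i == 0:  # edge (1,2), v1 -> v2: decreasing j
                tags.append(("edge", 1, p - j, r))
            else:  # edge (0,2), v0 -> v2: decreasing i
                tags.append(("edge", 2, p - i, r))
        else:
            tags.append(("interior", 0, r, r))
    order = []
    classification = []
    for v in range(3):
        for kind, ent, rank, r in tags:
            if kind == "vertex" and ent == v:
                order.append(r)
                classification.append(("vertex", v, 0))
    for e in range(3):
        edge_nodes = sorted([(rank, r) for kind, ent, rank, r in tags
                             if kind == "edge" and ent == e])
        for rank, r in edge_nodes:
            order.append(r)
            classification.append(("edge", e, rank - 1))
    for kind, ent, rank, r in tags:
        if kind == "interior":
            order.append(r)
            classification.append(("interior", 0, len([c for c in classification
                                                       if c[0] == "interior"])))
    return np.array(order), classification


class NodalBasis:
    """Lagrange basis on Gauss-Lobatto-type nodal points.

    ``classification`` tags each node (kind, entity, rank) in the canonical
    local ordering described in :func:`_warp_blend_triangle`.
    """

    def __init__(self, dimension: int, degree: int):
        if not 1 <= degree <= 6:
            raise ValueError(f"nodal degree must be in 1..6, got {degree}")
        self.dimension = dimension
        self.degree = degree
        if dimension == 1:
            glpts = gauss_lobatto_points_1d(degree)
            # canonical order: endpoints first, then interior left-to-right
            pts = np.concatenate([[glpts[0], glpts[-1]], glpts[1:-1]])
            self.points = pts.reshape(-1, 1)
            self.classification = ([("vertex", 0, 0), ("vertex", 1, 0)]
                                   + [("interior", 0, r) for r in range(degree - 1)])
        elif dimension == 2:
            pts, cls = _warp_blend_triangle(degree)
            self.points = pts
            self.classification = cls
        else:
            raise ValueError("dimension must be 1 or 2")
        self._V = self._ortho_eval(self.points)
        cond = np.linalg.cond(self._V)
        if not np.isfinite(cond) or cond > 1e12:
            raise RuntimeError("singular nodal Vandermonde: bad nodal set")

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def _ortho_eval(self, pts: np.ndarray) -> np.ndarray:
        """Orthogonal polynomial basis at pts; shape (n_pts, n_basis)."""
        p = self.degree
        if self.dimension == 1:
            x = 2.0 * np.asarray(pts).reshape(-1) - 1.0
            cols = [np.sqrt(k + 0.5) * eval_jacobi(k, 0.0, 0.0, x) for k in range(p + 1)]
            return np.column_stack(cols)
        pts = np.asarray(pts).reshape(-1, 2)
        # Dubiner basis on collapsed coordinates
        xx, yy = pts[:, 0], pts[:, 1]
        b = 2.0 * yy - 1.0
        denom = 1.0 - yy
        a = np.where(denom > 1e-14, 2.0 * xx / np.where(denom > 1e-14, denom, 1.0) - 1.0, -1.0)
        cols = []
        for i in range(p + 1):
            for j in range(p + 1 - i):
                Pi = eval_jacobi(i, 0.0, 0.0, a)
                Pj = eval_jacobi(j, 2.0 * i + 1.0, 0.0, b)
                cols.append(Pi * Pj * denom ** i)
        return np.column_stack(cols)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Cardinal (Lagrange) function values; shape (n_nodes, n_points)."""
        Psi = self._ortho_eval(points)  # (npts, nbasis)
        # cardinal_j(x) = sum_k inv(V)[k, j] psi_k(x)
        return np.linalg.solve(self._V.T, Psi.T)


def nodal_points(dimension: int, degree: int) -> NodalBasis:
    """Nodal basis of degree ``degree`` on Gauss-Lobatto-type points."""
    return NodalBasis(dimension, degree)


def hierarchical_basis_interval(p: int) -> HierarchicalBasis:
    """Hierarchical basis on [0, 1]: 1-x, x, then bubbles of degree 2..p."""
    return HierarchicalBasis(1, p)


def hierarchical_basis_triangle(p: int) -> HierarchicalBasis:
    """Hierarchical basis on the reference triangle (3/6/10/15 modes)."""
    return HierarchicalBasis(2, p)
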