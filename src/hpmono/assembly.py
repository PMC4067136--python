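"""Sparse operator assembly and the nodal<->hierarchical change of basis.

The right-hand side of the semidiscrete system is produced *matrix-based*:
the transmembrane current is interpolated on the degree-p_tilde
Gauss-Lobatto nodal set, its nodal values are converted element-locally to
hierarchical coefficients, and the load vector is then a single sparse
product with a rectangular "nested" mass matrix pairing the degree-p test
basis with the degree-p_tilde trial basis.  A direct Gauss-quadrature
assembler of the same load vector is kept as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .dof_numbering import DofMap
from .meshing import Mesh
from .reference_elements import (HierarchicalBasis, NodalBasis, gauss_rule,
                                 gauss_lobatto_points_1d)

__all__ = [
    "ElementTransforms",
    "NodalSpace",
    "AssembledOperators",
    "assemble_mass",
    "assemble_stiffness",
    "build_nodal_space",
    "evaluation_matrix",
    "nodal_to_hierarchical_matrix",
    "nodal_to_hierarchical",
    "rhs_matrix_based",
    "rhs_quadrature",
    "assemble_operators",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class ElementTransforms:
    """Per-element affine maps x = v0 + B x_ref."""

    origin: np.ndarray   # (T, dim)
    B: np.ndarray        # (T, dim, dim)
    Binv: np.ndarray     # (T, dim, dim)
    det: np.ndarray      # (T,)

    @classmethod
    def from_mesh(cls, mesh: Mesh) -> "ElementTransforms":
        v, t = mesh.vertices, mesh.elements
        if mesh.dim == 1:
            h = (v[t[:, 1], 0] - v[t[:, 0], 0])
            B = h.reshape(-1, 1, 1)
            return cls(origin=v[t[:, 0]], B=B, Binv=1.0 / B, det=h)
        B = np.stack([v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]], axis=2)
        det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
        Binv = np.empty_like(B)
        Binv[:, 0, 0] = B[:, 1, 1] / det
        Binv[:, 0, 1] = -B[:, 0, 1] / det
        Binv[:, 1, 0] = -B[:, 1, 0] / det
        Binv[:, 1, 1] = B[:, 0, 0] / det
        return cls(origin=v[t[:, 0]], B=B, Binv=Binv, det=det)

    def map_points(self, ref_pts: np.ndarray) -> np.ndarray:
        """Map reference points to every element; (T, n_pts, dim)."""
        return self.origin[:, None, :] + np.einsum("tab,pb->tpa", self.B, ref_pts)


def _normalize_conductivity(conductivity, dim: int):
    """Return a callable points -> (n,) in 1D or (n, 2, 2) in 2D."""
    if callable(conductivity):
        return conductivity
    arr = np.asarray(conductivity, dtype=float)
    if dim == 1:
        return lambda pts: np.full(len(pts), float(arr))
    if arr.ndim == 0:
        arr = float(arr) * np.eye(2)
    return lambda pts: np.broadcast_to(arr, (len(pts), 2, 2))


# ---------------------------------------------------------------------------
# global nodal (Gauss-Lobatto) point space for the cell states
# ---------------------------------------------------------------------------

@dataclass
class NodalSpace:
    """Global continuous degree-p_tilde nodal point set over a mesh."""

    mesh: Mesh
    degree: int
    basis: NodalBasis
    n_nodes: int
    coords: np.ndarray       # (n_nodes, dim)
    cell_nodes: np.ndarray   # (T, n_local) global node index of local node
    node_owner: np.ndarray   # (n_nodes,) owning element (first toucher)


def build_nodal_space(mesh: Mesh, p_tilde: int) -> NodalSpace:
    basis = NodalBasis(mesh.dim, p_tilde)
    T = mesh.n_elements
    V = mesh.n_vertices
    if mesh.dim == 1:
        ni = p_tilde - 1
        n_nodes = V + ni * T
        cell_nodes = np.column_stack(
            [mesh.elements[:, 0], mesh.elements[:, 1]]
            + [V + np.arange(T) * ni + k for k in range(ni)])
        tf = ElementTransforms.from_mesh(mesh)
        coords = np.empty((n_nodes, 1))
        coords[:V] = mesh.vertices
        phys = tf.map_points(basis.points)  # (T, n_loc, 1)
        coords[V:] = phys[:, 2:, :].reshape(-1, 1)
    else:
        ne = p_tilde - 1
        ni = (p_tilde - 1) * (p_tilde - 2) // 2
        E = mesh.n_edges
        n_nodes = V + ne * E + ni * T
        cols = [mesh.elements[:, 0], mesh.elements[:, 1], mesh.elements[:, 2]]
        from .reference_elements import LOCAL_EDGES
        for e, (a, b) in enumerate(LOCAL_EDGES):
            ge = mesh.element_edges[:, e]
            agrees = mesh.elements[:, a] < mesh.elements[:, b]
            for k in range(ne):
                kk = np.where(agrees, k, ne - 1 - k)
                cols.append(V + ge * ne + kk)
        for k in range(ni):
            cols.append(V + ne * E + np.arange(T) * ni + k)
        cell_nodes = np.column_stack(cols) if cols else np.zeros((T, 0), np.int64)
        coords = np.empty((n_nodes, 2))
        coords[:V] = mesh.vertices
        glpar = gauss_lobatto_points_1d(p_tilde)[1:-1] if ne else np.zeros(0)
        lo = mesh.vertices[mesh.edges[:, 0]]
        hi = mesh.vertices[mesh.edges[:, 1]]
        for k in range(ne):
            coords[V + np.arange(E) * ne + k] = lo + glpar[k] * (hi - lo)
        if ni:
            tf = ElementTransforms.from_mesh(mesh)
            n_loc = basis.n_nodes
            phys = tf.map_points(basis.points[n_loc - ni:])
            coords[V + ne * E:] = phys.reshape(-1, 2)
    cell_nodes = cell_nodes.astype(np.int64)
    owner = np.full(n_nodes, -1, np.int64)
    for t in range(T - 1, -1, -1):
        owner[cell_nodes[t]] = t
    return NodalSpace(mesh=mesh, degree=p_tilde, basis=basis, n_nodes=n_nodes,
                      coords=coords, cell_nodes=cell_nodes, node_owner=owner)


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

def _scatter(rows, cols, data, shape):
    return sp.csr_matrix(sp.coo_matrix(
        (data.ravel(), (rows.ravel(), cols.ravel())), shape=shape))


def assemble_mass(mesh: Mesh, dofmap: DofMap) -> sp.csr_matrix:
    """Galerkin mass matrix (phi_i, phi_j), exact by quadrature."""
    p = dofmap.p
    basis = HierarchicalBasis(mesh.dim, p)
    rule = gauss_rule(mesh.dim, 2 * p)
    Phi = basis.evaluate(rule.points)            # (n_modes, nq)
    Mref = (Phi * rule.weights) @ Phi.T          # (n_modes, n_modes)
    tf = ElementTransforms.from_mesh(mesh)
    s = dofmap.cell_signs                        # (T, n_modes)
    data = tf.det[:, None, None] * (s[:, :, None] * s[:, None, :]) * Mref
    cd = dofmap.cell_dofs
    n_modes = Phi.shape[0]
    rows = np.repeat(cd, n_modes, axis=1)
    cols = np.tile(cd, (1, n_modes))
    return _scatter(rows, cols, data, (dofmap.n_dofs, dofmap.n_dofs))


def assemble_stiffness(mesh: Mesh, dofmap: DofMap, conductivity,
                       unit_scale: float = 1.0,
                       extra_exactness: int = 2) -> sp.csr_matrix:
    """Stiffness matrix (sigma grad phi_i, grad phi_j), with the
    conductivity read pointwise at each Gauss point.

    ``unit_scale`` multiplies sigma (e.g. S/m -> mS/cm is a factor 10).
    """
    p = dofmap.p
    basis = HierarchicalBasis(mesh.dim, p)
    rule = gauss_rule(mesh.dim, 2 * (p - 1) + extra_exactness)
    G = basis.gradients(rule.points)             # (n_modes, nq, dim)
    tf = ElementTransforms.from_mesh(mesh)
    sig_fn = _normalize_conductivity(conductivity, mesh.dim)
    qpts = tf.map_points(rule.points)            # (T, nq, dim)
    T = mesh.n_elements
    nq = len(rule.weights)
    sig = np.asarray(sig_fn(qpts.reshape(-1, mesh.dim)), dtype=float) * unit_scale
    if mesh.dim == 1:
        sig = sig.reshape(T, nq)
        Gp = G[None, :, :, 0] * tf.Binv[:, None, 0, :]      # (T, n_modes, nq)
        w = rule.weights[None, None, :] * sig[:, None, :] * tf.det[:, None, None]
        data = np.einsum("tiq,tjq->tij", Gp * w, Gp)
    else:
        sig = sig.reshape(T, nq, 2, 2)
        _check_spd(sig, qpts)
        Gp = np.einsum("mqa,tab->tmqb", G, tf.Binv)          # (T, n_modes, nq, 2)
        SGp = np.einsum("tqab,tjqb->tjqa", sig, Gp)
        data = np.einsum("tiqa,tjqa,q,t->tij", Gp, SGp, rule.weights, tf.det)
    s = dofmap.cell_signs
    data = data * (s[:, :, None] * s[:, None, :])
    cd = dofmap.cell_dofs
    n_modes = G.shape[0]
    rows = np.repeat(cd, n_modes, axis=1)
    cols = np.tile(cd, (1, n_modes))
    return _scatter(rows, cols, data, (dofmap.n_dofs, dofmap.n_dofs))


def _check_spd(sig: np.ndarray, qpts: np.ndarray):
    tr = sig[..., 0, 0] + sig[..., 1, 1]
    det = sig[..., 0, 0] * sig[..., 1, 1] - sig[..., 0, 1] * sig[..., 1, 0]
    asym = np.abs(sig[..., 0, 1] - sig[..., 1, 0])
    bad = (tr <= 0) | (det <= 0) | (asym > 1e-10 * (np.abs(tr) + 1.0))
    if bad.any():
        t, q = np.argwhere(bad)[0]
        raise ValueError(f"conductivity not SPD at quadrature point "
                         f"{qpts[t, q]} (element {t})")


# ---------------------------------------------------------------------------
# nodal <-> hierarchical
# ---------------------------------------------------------------------------

def evaluation_matrix(mesh: Mesh, dofmap: DofMap, nodal: NodalSpace) -> sp.csr_matrix:
    """Sparse (n_nodes x N_p) operator evaluating a hierarchical field at
    every global nodal point."""
    basis = HierarchicalBasis(mesh.dim, dofmap.p)
    Phi = basis.evaluate(nodal.basis.points)     # (n_modes, n_loc)
    T = mesh.n_elements
    n_loc = nodal.basis.n_nodes
    n_modes = Phi.shape[0]
    own = nodal.node_owner[nodal.cell_nodes] == np.arange(T)[:, None]  # (T, n_loc)
    data = (dofmap.cell_signs[:, None, :] * Phi.T[None, :, :]) * own[:, :, None]
    rows = np.broadcast_to(nodal.cell_nodes[:, :, None], (T, n_loc, n_modes))
    cols = np.broadcast_to(dofmap.cell_dofs[:, None, :], (T, n_loc, n_modes))
    return _scatter(rows, cols, data, (nodal.n_nodes, dofmap.n_dofs))


def _dof_owner(dofmap: DofMap) -> np.ndarray:
    owner = np.full(dofmap.n_dofs, -1, np.int64)
    for t in range(dofmap.mesh.n_elements - 1, -1, -1):
        owner[dofmap.cell_dofs[t]] = t
    return owner


def nodal_to_hierarchical_matrix(mesh: Mesh, dofmap_pt: DofMap,
                                 nodal: NodalSpace) -> sp.csr_matrix:
    """Sparse (N_pt x n_nodes) operator turning nodal values into the
    hierarchical coefficients of the continuous degree-p_tilde interpolant."""
    if dofmap_pt.p != nodal.degree:
        raise ValueError("dofmap degree must equal nodal degree")
    basis = HierarchicalBasis(mesh.dim, dofmap_pt.p)
    Vref = basis.evaluate(nodal.basis.points).T  # (n_loc, n_modes)
    W = np.linalg.inv(Vref)                      # (n_modes, n_loc)
    T = mesh.n_elements
    n_modes, n_loc = W.shape
    owner = _dof_owner(dofmap_pt)
    own = owner[dofmap_pt.cell_dofs] == np.arange(T)[:, None]   # (T, n_modes)
    data = (dofmap_pt.cell_signs[:, :, None] * W[None, :, :]) * own[:, :, None]
    rows = np.broadcast_to(dofmap_pt.cell_dofs[:, :, None], (T, n_modes, n_loc))
    cols = np.broadcast_to(nodal.cell_nodes[:, None, :], (T, n_modes, n_loc))
    return _scatter(rows, cols, data, (dofmap_pt.n_dofs, nodal.n_nodes))


def nodal_to_hierarchical(values: np.ndarray, mesh: Mesh, dofmap_pt: DofMap,
                          nodal: NodalSpace, check: bool = False) -> np.ndarray:
    """Hierarchical coefficients of the continuous interpolant matching
    ``values`` at every nodal point.

    With ``check=True`` the per-element coefficient sets are compared on
    shared entities; disagreement beyond 1e-9 signals an orientation bug.
    """
    Tmat = nodal_to_hierarchical_matrix(mesh, dofmap_pt, nodal)
    coeffs = Tmat @ values
    if check:
        basis = HierarchicalBasis(mesh.dim, dofmap_pt.p)
        Vref = basis.evaluate(nodal.basis.points).T
        W = np.linalg.inv(Vref)
        local_vals = values[nodal.cell_nodes]                     # (T, n_loc)
        local_c = dofmap_pt.cell_signs * (local_vals @ W.T)       # (T, n_modes)
        spread = np.abs(local_c - coeffs[dofmap_pt.cell_dofs])
        if spread.max() > 1e-9 * max(1.0, np.abs(values).max()):
            t, m = np.unravel_index(np.argmax(spread), spread.shape)
            raise RuntimeError(
                f"shared-mode coefficient mismatch {spread.max():.3e} at "
                f"element {t}, local mode {m} (edge orientation bug?)")
    return coeffs


def rhs_matrix_based(Mtilde: sp.spmatrix, coeffs: np.ndarray) -> np.ndarray:
    """Load vector I_j = (iota I_total, phi_j) as a single sparse product."""
    if Mtilde.shape[1] != len(coeffs):
        raise ValueError("coefficient vector does not match nested mass")
    return Mtilde @ coeffs


def rhs_quadrature(mesh: Mesh, dofmap: DofMap, nodal: NodalSpace,
                   values: np.ndarray) -> np.ndarray:
    """Oracle: assemble (iota I_total, phi_j) by direct Gauss quadrature,
    element by element (the computationally heavier alternative)."""
    p = dofmap.p
    basis = HierarchicalBasis(mesh.dim, p)
    rule = gauss_rule(mesh.dim, p + nodal.degree)
    Phi = basis.evaluate(rule.points)              # (n_modes, nq)
    C = nodal.basis.evaluate(rule.points)          # (n_loc, nq)
    tf = ElementTransforms.from_mesh(mesh)
    local_vals = values[nodal.cell_nodes]          # (T, n_loc)
    Iq = local_vals @ C                            # (T, nq)
    r = np.einsum("tq,jq,q,t->tj", Iq, Phi, rule.weights, tf.det)
    r = r * dofmap.cell_signs
    out = np.zeros(dofmap.n_dofs)
    np.add.at(out, dofmap.cell_dofs.ravel(), r.ravel())
    return out


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class AssembledOperators:
    """Everything the time stepper needs, assembled once."""

    dofmap: DofMap
    dofmap_pt: DofMap
    nodal: NodalSpace
    M: sp.csr_matrix          # degree-p mass
    A: sp.csr_matrix          # degree-p stiffness with conductivity
    Mtilde: sp.csr_matrix     # (N_p x N_pt) nested rectangular mass
    Eval: sp.csr_matrix       # (n_nodes x N_p) point evaluation
    Tmat: sp.csr_matrix       # (N_pt x n_nodes) nodal -> hierarchical

    def linear_block(self, K: sp.spmatrix) -> sp.csr_matrix:
        V = self.dofmap.n_vertex_dofs
        return sp.csr_matrix(K)[:V, :V]


def assemble_operators(mesh: Mesh, p: int, p_tilde: int, conductivity,
                       unit_scale: float = 1.0) -> AssembledOperators:
    """Assemble the full operator bundle for a simulation.

    Full-order convergence requires p_tilde >= p; smaller p_tilde (the
    cell states coarser than the potential) is permitted — it reproduces
    the order-limited scheme — as is p_tilde > p.  The matrix-based
    right-hand side needs p_tilde <= 4 (the hierarchical trial space tops
    out at degree 4).
    """
    dofmap = DofMap(mesh, p)
    dofmap_pt = DofMap(mesh, p_tilde)
    nodal = build_nodal_space(mesh, p_tilde)
    M = assemble_mass(mesh, dofmap)
    A = assemble_stiffness(mesh, dofmap, conductivity, unit_scale=unit_scale)
    dofmap_q = dofmap if p >= p_tilde else dofmap_pt
    Mq = M if dofmap_q is dofmap else assemble_mass(mesh, dofmap_q)
    Mtilde = sp.csr_matrix(Mq)[dofmap.embed_indices(dofmap_q), :][
        :, dofmap_pt.embed_indices(dofmap_q)]
    Eval = evaluation_matrix(mesh, dofmap, nodal)
    Tmat = nodal_to_hierarchical_matrix(mesh, dofmap_pt, nodal)
    return AssembledOperators(dofmap=dofmap, dofmap_pt=dofmap_pt, nodal=nodal,
                              M=M, A=A, Mtilde=Mtilde, Eval=Eval, Tmat=Tmat)
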