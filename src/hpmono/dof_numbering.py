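"""Global degree-of-freedom maps for the hierarchical spaces.

Numbering convention: all vertex modes first (global index = vertex index),
then edge modes grouped by edge and ordered by mode degree, then interior
modes grouped by element and ordered by degree.  The vertex modes therefore
form a leading principal block, which is what the linear-block ILU
preconditioner extracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import Mesh

__all__ = ["DofMap", "count_dofs", "count_dofs_from_entities",
           "linear_block_indices", "interior_mode_count"]

#: interior hierarchical modes per triangle at degree p
_I2D = {1: 0, 2: 0, 3: 1, 4: 3}


def interior_mode_count(dim: int, p: int) -> int:
    if dim == 1:
        return p - 1  # 1D bubbles live on the element
    return _I2D[p]


def count_dofs_from_entities(n_vertices: int, n_edges: int, n_elements: int,
                             p: int, dim: int = 2) -> int:
    """N = V + (p-1) E + i(p) T in 2D; N = V + (p-1) T in 1D."""
    if not 1 <= p <= 4:
        raise ValueError("p must be in 1..4")
    if dim == 1:
        return n_vertices + (p - 1) * n_elements
    return n_vertices + (p - 1) * n_edges + _I2D[p] * n_elements


def count_dofs(mesh: Mesh, p: int) -> int:
    return count_dofs_from_entities(mesh.n_vertices, mesh.n_edges,
                                    mesh.n_elements, p, mesh.dim)


@dataclass
class DofMap:
    """Global numbering of the hierarchical modes of degree ``p``."""

    mesh: Mesh
    p: int

    def __post_init__(self):
        if not 1 <= self.p <= 4:
            raise ValueError("p must be in 1..4")
        m, p = self.mesh, self.p
        self.n_vertex_dofs = m.n_vertices
        if m.dim == 1:
            self.n_edge_dofs = 0
            self.n_interior_dofs = (p - 1) * m.n_elements
        else:
            self.n_edge_dofs = (p - 1) * m.n_edges
            self.n_interior_dofs = _I2D[p] * m.n_elements
        self.n_dofs = self.n_vertex_dofs + self.n_edge_dofs + self.n_interior_dofs
        self._edge0 = self.n_vertex_dofs
        self._int0 = self.n_vertex_dofs + self.n_edge_dofs
        self._cell_dofs = self._build_cell_dofs()
        self._cell_signs = self._build_cell_signs()

    # -- per-element connectivity -----------------------------------------
    def _build_cell_dofs(self) -> np.ndarray:
        """(T, n_local) global dof of each local mode, in the local
        hierarchical (prefix) ordering of reference_elements."""
        m, p = self.mesh, self.p
        T = m.n_elements
        if m.dim == 1:
            cols = [m.elements[:, 0], m.elements[:, 1]]
            for d in range(2, p + 1):
                cols.append(self._int0 + np.arange(T) * (p - 1) + (d - 2))
            return np.column_stack(cols).astype(np.int64)
        cols = [m.elements[:, 0], m.elements[:, 1], m.elements[:, 2]]
        ee = m.element_edges  # (T, 3)
        if p >= 2:
            for e in range(3):
                cols.append(self._edge0 + ee[:, e] * (p - 1) + 0)
        if p >= 3:
            for e in range(3):
                cols.append(self._edge0 + ee[:, e] * (p - 1) + 1)
            cols.append(self._int0 + np.arange(T) * _I2D[p] + 0)
        if p >= 4:
            for e in range(3):
                cols.append(self._edge0 + ee[:, e] * (p - 1) + 2)
            cols.append(self._int0 + np.arange(T) * _I2D[p] + 1)
            cols.append(self._int0 + np.arange(T) * _I2D[p] + 2)
        return np.column_stack(cols).astype(np.int64)

    def _build_cell_signs(self) -> np.ndarray:
        """(T, n_local) sign of each local mode: odd edge modes flip when
        the local canonical edge direction opposes the global (low->high
        vertex index) orientation."""
        m, p = self.mesh, self.p
        signs = np.ones_like(self._cell_dofs, dtype=float)
        if m.dim == 1 or p < 3:
            return signs
        from .reference_elements import LOCAL_EDGES
        for e, (a, b) in enumerate(LOCAL_EDGES):
            flip = m.elements[:, a] > m.elements[:, b]
            signs[flip, 6 + e] = -1.0  # cubic edge modes sit at local 6..8
        return signs

    @property
    def cell_dofs(self) -> np.ndarray:
        return self._cell_dofs

    @property
    def cell_signs(self) -> np.ndarray:
        return self._cell_signs

    def edge_orientation_agrees(self) -> np.ndarray:
        """(T, 3) bool: local canonical direction matches global."""
        from .reference_elements import LOCAL_EDGES
        m = self.mesh
        out = np.ones((m.n_elements, 3), bool)
        for e, (a, b) in enumerate(LOCAL_EDGES):
            out[:, e] = m.elements[:, a] < m.elements[:, b]
        return out

    # -- index sets --------------------------------------------------------
    def linear_block_indices(self) -> np.ndarray:
        """Vertex-mode global indices (a leading prefix)."""
        return np.arange(self.n_vertex_dofs)

    def embed_indices(self, finer: "DofMap") -> np.ndarray:
        """For each dof of self (degree p), its index in ``finer`` (degree
        p' >= p on the same mesh).  Valid because mode lists nest."""
        if finer.mesh is not self.mesh or finer.p < self.p:
            raise ValueError("finer map must share the mesh with degree >= p")
        p, q = self.p, finer.p
        idx = np.empty(self.n_dofs, np.int64)
        V = self.n_vertex_dofs
        idx[:V] = np.arange(V)
        if self.mesh.dim == 1:
            T = self.mesh.n_elements
            for d in range(2, p + 1):
                mine = self._int0 + np.arange(T) * (p - 1) + (d - 2)
                theirs = finer._int0 + np.arange(T) * (q - 1) + (d - 2)
                idx[mine] = theirs
            return idx
        E = self.mesh.n_edges
        T = self.mesh.n_elements
        for k in range(p - 1):
            mine = self._edge0 + np.arange(E) * (p - 1) + k
            theirs = finer._edge0 + np.arange(E) * (q - 1) + k
            idx[mine] = theirs
        for k in range(_I2D[p]):
            mine = self._int0 + np.arange(T) * _I2D[p] + k
            theirs = finer._int0 + np.arange(T) * _I2D[q] + k
            idx[mine] = theirs
        return idx


def linear_block_indices(dofmap: DofMap) -> np.ndarray:
    return dofmap.linear_block_indices()
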