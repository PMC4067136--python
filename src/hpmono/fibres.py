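"""Conductivity tensor fields built from fibre direction fields.

The tissue conducts fastest along the local myocyte (fibre) direction f:
sigma = sigma_t I + (sigma_l - sigma_t) f f^T, so the tensor's eigenvalues
are exactly {sigma_l, sigma_t} everywhere.  Fibre fields available:

* a fixed axis,
* an angle field given by a bivariate cubic polynomial (rapidly rotating
  fibres),
* a rule-based Laplace-Dirichlet field: solve Laplace's equation with +1 /
  -1 Dirichlet data on two opposite external edges and zero-flux conditions
  elsewhere (including hole boundaries), then take f = normalised gradient.
  The no-flux condition makes the gradient tangent to hole boundaries, the
  way real fibres negotiate around blood vessels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse.linalg as spla

from .assembly import ElementTransforms, assemble_stiffness
from .dof_numbering import DofMap
from .meshing import Mesh

__all__ = [
    "ConductivityField",
    "tensor_from_fibre",
    "uniform_fibre_field",
    "cubic_angle_field",
    "laplace_dirichlet_fibres",
    "LaplaceFibreField",
    "DEFAULT_CUBIC_COEFFS",
]


@dataclass
class ConductivityField:
    """x -> sigma(x), symmetric with eigenvalues {sigma_l, sigma_t} (S/m)."""

    sigma_l: float
    sigma_t: float
    fibre: Callable  # points (n, 2) -> unit directions (n, 2)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        f = np.asarray(self.fibre(points), dtype=float)
        norms = np.linalg.norm(f, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-length fibre vector")
        f = f / norms[:, None]
        out = self.sigma_t * np.broadcast_to(np.eye(2), (len(points), 2, 2)).copy()
        out += (self.sigma_l - self.sigma_t) * np.einsum("na,nb->nab", f, f)
        return out


def tensor_from_fibre(fibre: Callable, sigma_l: float, sigma_t: float) -> ConductivityField:
    """sigma = sigma_t I + (sigma_l - sigma_t) f f^T with unit fibre field f."""
    if not sigma_l >= sigma_t > 0:
        raise ValueError("need sigma_l >= sigma_t > 0")
    return ConductivityField(sigma_l=sigma_l, sigma_t=sigma_t, fibre=fibre)


def uniform_fibre_field(direction=(1.0, 0.0)) -> Callable:
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero-length fibre vector")
    d = d / n

    def field(points):
        return np.broadcast_to(d, (len(points), 2))
    return field


#: demo coefficients: theta = (pi/2)(s(x) + s(y)) with s the cubic smoothstep,
#: sweeping the fibre angle through 180 degrees across the unit square
DEFAULT_CUBIC_COEFFS = {
    (2, 0): 1.5 * np.pi, (3, 0): -np.pi,
    (0, 2): 1.5 * np.pi, (0, 3): -np.pi,
}


def cubic_angle_field(coefficients: dict | None = None) -> Callable:
    """Fibre direction (cos theta, sin theta) with theta a bivariate cubic.

    ``coefficients`` maps (i, j) -> c for terms c * x^i * y^j, i + j <= 3.
    Zero coefficients give uniform x-aligned fibres.
    """
    coeffs = DEFAULT_CUBIC_COEFFS if coefficients is None else coefficients
    for (i, j) in coeffs:
        if i + j > 3:
            raise ValueError("angle polynomial must have total degree <= 3")

    def field(points):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        x, y = points[:, 0], points[:, 1]
        theta = np.zeros(len(points))
        for (i, j), c in coeffs.items():
            theta += c * x ** i * y ** j
        return np.column_stack([np.cos(theta), np.sin(theta)])
    return field


class LaplaceFibreField:
    """Fibre directions f = grad(phi)/|grad(phi)| from a harmonic potential.

    Where the gradient is degenerate (below ``degenerate_frac`` of the
    largest gradient magnitude in the evaluated batch — the stagnation
    zones where a flow-based fibre direction is genuinely undefined), the
    direction is taken from the nearest non-degenerate point and the point
    is recorded in ``degenerate_points``.
    """

    def __init__(self, grad_at: Callable, degenerate_frac: float = 0.15):
        self._grad_at = grad_at
        self.degenerate_frac = degenerate_frac
        self.degenerate_points: list = []

    def gradient(self, points: np.ndarray) -> np.ndarray:
        return self._grad_at(np.asarray(points, dtype=float).reshape(-1, 2))

    def degenerate_mask(self, points: np.ndarray) -> np.ndarray:
        g = self.gradient(points)
        mags = np.linalg.norm(g, axis=1)
        return mags < self.degenerate_frac * mags.max()

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        g = self.gradient(points)
        mags = np.linalg.norm(g, axis=1)
        bad = mags < self.degenerate_frac * mags.max()
        if bad.all():
            raise RuntimeError("potential gradient degenerate everywhere")
        if bad.any():
            self.degenerate_points.append(points[bad])
            goodidx = np.nonzero(~bad)[0]
            for i in np.nonzero(bad)[0]:
                j = goodidx[np.argmin(np.linalg.norm(points[goodidx] - points[i],
                                                     axis=1))]
                g[i] = g[j]
                mags[i] = mags[j]
        return g / mags[:, None]


def laplace_dirichlet_fibres(mesh: Mesh, inlet_edge_tag: str,
                             outlet_edge_tag: str, degree: int = 2):
    """Rule-based fibre field from a Laplace-Dirichlet solve.

    The potential phi solves Laplace's equation with phi = +1 on the inlet
    edges, -1 on the outlet edges, natural (zero-Neumann) conditions
    elsewhere — including hole boundaries, which makes grad(phi) tangent to
    the holes; f(x) = grad phi / |grad phi| evaluated in the element
    containing x.  Returns (field, phi_vertex_values).
    """
    for tag in (inlet_edge_tag, outlet_edge_tag):
        if tag not in mesh.boundary_tags or len(mesh.boundary_tags[tag]) == 0:
            raise ValueError(f"no boundary edges tagged {tag!r}")
    inlet = mesh.boundary_tags[inlet_edge_tag]
    outlet = mesh.boundary_tags[outlet_edge_tag]
    if np.intersect1d(mesh.edges[inlet].ravel(), mesh.edges[outlet].ravel()).size:
        raise ValueError("inlet and outlet edges must be disjoint")

    dofmap = DofMap(mesh, degree)
    A = assemble_stiffness(mesh, dofmap, 1.0).tolil()
    N = dofmap.n_dofs
    rhs = np.zeros(N)
    fixed = {}
    for tag, val in ((inlet_edge_tag, 1.0), (outlet_edge_tag, -1.0)):
        vs = np.unique(mesh.edges[mesh.boundary_tags[tag]].ravel())
        for v in vs:
            fixed[int(v)] = val
        if degree >= 2:  # edge-mode dofs on Dirichlet edges carry no deviation
            for e in mesh.boundary_tags[tag]:
                for k in range(degree - 1):
                    fixed[int(mesh.n_vertices + e * (degree - 1) + k)] = 0.0
    A = A.tocsr()
    free = np.setdiff1d(np.arange(N), np.fromiter(fixed, dtype=np.int64))
    xfix = np.zeros(N)
    for d, val in fixed.items():
        xfix[d] = val
    rhs_free = rhs[free] - A[free] @ xfix
    Aff = A[free][:, free]
    try:
        sol_free = spla.spsolve(Aff.tocsc(), rhs_free)
    except Exception as exc:  # pragma: no cover - singular only on bad tags
        raise RuntimeError(f"singular Laplace system (check tags): {exc}")
    phi = xfix.copy()
    phi[free] = sol_free

    tf = ElementTransforms.from_mesh(mesh)
    from .reference_elements import HierarchicalBasis
    basis = HierarchicalBasis(2, degree)
    cell_phi = dofmap.cell_signs * phi[dofmap.cell_dofs]      # (T, n_modes)

    def grad_at(points):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        elems = _locate(mesh, tf, points)
        # reference coordinates of each point in its element
        local = np.einsum("nab,nb->na", tf.Binv[elems],
                          points - tf.origin[elems])
        G = basis.gradients(local)                    # (n_modes, n, 2)
        Gp = np.einsum("mna,nab->mnb", G, tf.Binv[elems])
        return np.einsum("nm,mna->na", cell_phi[elems], Gp)

    return LaplaceFibreField(grad_at), phi[:mesh.n_vertices]


def _locate(mesh: Mesh, tf: ElementTransforms, points: np.ndarray) -> np.ndarray:
    """Element index containing each point (nearest element if outside)."""
    # a full barycentric test against all elements is memory-heavy;
    # shortlist candidates with a centroid kd-tree instead
    from scipy.spatial import cKDTree
    cent = mesh.element_centroids()
    tree = cKDTree(cent)
    k = min(12, mesh.n_elements)
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    out = np.empty(len(points), np.int64)
    for i, p in enumerate(points):
        chosen = cand[i, 0]
        best = -1e30
        for t in cand[i]:
            loc = tf.Binv[t] @ (p - tf.origin[t])
            margin = min(loc[0], loc[1], 1.0 - loc[0] - loc[1])
            if margin > -1e-12:
                chosen = t
                break
            if margin > best:
                best = margin
                chosen = t
        out[i] = chosen
    return out
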