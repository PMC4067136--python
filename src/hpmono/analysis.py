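"""Post-processing: activation times, conduction velocities, error norms
and convergence slopes.

Conduction velocity conventions follow the usual wavefront bookkeeping:
activation at a point is the first linearly interpolated upcrossing of
0 mV; 1D CV uses the probes at 2 cm and 4 cm of the 6 cm strand; 2D CV is
the mean over seeded random vertex pairs of (separation along the
propagation axis) / (activation-time difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import Mesh
from .reference_elements import HierarchicalBasis, gauss_rule

__all__ = [
    "ErrorRecord",
    "CvRecord",
    "activation_time",
    "cv_1d",
    "cv_2d",
    "evaluate_1d",
    "error_norms",
    "convergence_slope",
]


@dataclass(frozen=True)
class ErrorRecord:
    """One point of an error-vs-h study."""

    h: float
    p: int
    p_tilde: int
    norm: str          # "Linf_L2" or "L2_H1"
    error: float
    reference: str = ""


@dataclass(frozen=True)
class CvRecord:
    descriptor: str
    t_probe_a: float
    t_probe_b: float
    cv: float                    # cm/s
    pct_error: float | None = None


def activation_time(times: np.ndarray, u: np.ndarray) -> float | None:
    """First upcrossing of 0 mV, linearly interpolated; None if never."""
    times = np.asarray(times, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    up = (u[:-1] < 0.0) & (u[1:] >= 0.0)
    idx = np.nonzero(up)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    frac = -u[i] / (u[i + 1] - u[i])
    return float(times[i] + frac * (times[i + 1] - times[i]))


def cv_1d(t_at_2cm: float, t_at_4cm: float) -> float:
    """2 cm / transit time, in cm/s."""
    if not t_at_4cm > t_at_2cm:
        raise ValueError("probe at 4 cm must activate after the one at 2 cm")
    return 2.0 / (t_at_4cm - t_at_2cm) * 1000.0


def cv_2d(activation: np.ndarray, mesh: Mesh, n_pairs: int = 500,
          seed: int = 0, axis: int = 1, min_separation: float = 0.2,
          min_dt: float = 0.5) -> float:
    """Mean random-pair CV (cm/s) for a planar wave along ``axis``.

    Pairs need both vertices activated, separation along the propagation
    axis >= ``min_separation`` cm and activation-time difference >=
    ``min_dt`` ms; deterministic for a fixed seed.
    """
    act = np.asarray(activation, dtype=float)
    coord = mesh.vertices[:, axis]
    ok = np.isfinite(act)
    ids = np.nonzero(ok)[0]
    rng = np.random.default_rng(seed)
    # draw candidates in bulk, keep admissible ones
    cvs = []
    attempts = 0
    while len(cvs) < n_pairs and attempts < 200 * n_pairs:
        a, b = rng.choice(ids, 2, replace=False)
        attempts += 1
        dy = abs(coord[a] - coord[b])
        dt = abs(act[a] - act[b])
        if dy >= min_separation and dt >= min_dt:
            cvs.append(dy / dt * 1000.0)
    if len(cvs) < 10:
        raise ValueError("fewer than 10 admissible vertex pairs")
    return float(np.mean(cvs))


# ---------------------------------------------------------------------------
# error norms (1D studies)
# ---------------------------------------------------------------------------

def evaluate_1d(mesh: Mesh, p: int, coeffs: np.ndarray, x: np.ndarray,
                deriv: int = 0) -> np.ndarray:
    """Evaluate a 1D hierarchical field (or its derivative) at points x."""
    x = np.asarray(x, dtype=float).reshape(-1)
    verts = mesh.vertices[:, 0]
    elem = np.clip(np.searchsorted(verts, x, side="right") - 1, 0,
                   mesh.n_elements - 1)
    x0 = verts[mesh.elements[elem, 0]]
    h = verts[mesh.elements[elem, 1]] - x0
    local = (x - x0) / h
    basis = HierarchicalBasis(1, p)
    if deriv == 0:
        Phi = basis.evaluate(local)                  # (n_modes, n)
    else:
        Phi = basis.gradients(local)[:, :, 0] / h    # chain rule
    # local dofs: [left vertex, right vertex, bubbles...]
    out = np.zeros_like(x)
    dm_cols = [mesh.elements[elem, 0], mesh.elements[elem, 1]]
    V = mesh.n_vertices
    for d in range(2, p + 1):
        dm_cols.append(V + elem * (p - 1) + (d - 2))
    for m, col in enumerate(dm_cols):
        out += coeffs[col] * Phi[m]
    return out


def error_norms(mesh_c: Mesh, p_c: int, snaps_c: list, mesh_r: Mesh,
                p_r: int, snaps_r: list, times: np.ndarray):
    """L^inf(L^2) and L^2(H^1) errors of a coarse 1D solution against a
    reference, both sampled at the same ``times``.

    Spatial integrals use the reference mesh's Gauss points; the time
    reduction is max-in-time for the L2 norm and trapezoid-in-time of the
    squared H1 norm (then square root).
    """
    if len(snaps_c) != len(times) or len(snaps_r) != len(times):
        raise ValueError("snapshot lists must match the sample times")
    span_c = (mesh_c.vertices[0, 0], mesh_c.vertices[-1, 0])
    span_r = (mesh_r.vertices[0, 0], mesh_r.vertices[-1, 0])
    if not np.allclose(span_c, span_r):
        raise ValueError("incompatible domains")
    rule = gauss_rule(1, 2 * max(p_c, p_r))
    verts = mesh_r.vertices[:, 0]
    h_r = np.diff(verts)
    x = (verts[:-1, None] + h_r[:, None] * rule.points[:, 0][None, :]).ravel()
    w = (h_r[:, None] * rule.weights[None, :]).ravel()
    l2 = np.empty(len(times))
    h1sq = np.empty(len(times))
    for k in range(len(times)):
        d0 = (evaluate_1d(mesh_c, p_c, snaps_c[k], x)
              - evaluate_1d(mesh_r, p_r, snaps_r[k], x))
        d1 = (evaluate_1d(mesh_c, p_c, snaps_c[k], x, deriv=1)
              - evaluate_1d(mesh_r, p_r, snaps_r[k], x, deriv=1))
        l2[k] = np.sqrt(w @ d0 ** 2)
        h1sq[k] = w @ (d0 ** 2 + d1 ** 2)
    linf_l2 = float(l2.max())
    l2_h1 = float(np.sqrt(np.trapezoid(h1sq, times)))
    ref = f"p={p_r}, h={np.max(h_r):.5g}"
    return (ErrorRecord(h=float(np.max(np.diff(mesh_c.vertices[:, 0]))),
                        p=p_c, p_tilde=0, norm="Linf_L2", error=linf_l2,
                        reference=ref),
            ErrorRecord(h=float(np.max(np.diff(mesh_c.vertices[:, 0]))),
                        p=p_c, p_tilde=0, norm="L2_H1", error=l2_h1,
                        reference=ref))


def convergence_slope(records) -> float:
    """Least-squares slope of log(error) vs log(h); needs >= 3 distinct h."""
    hs = np.array([r.h for r in records], dtype=float)
    errs = np.array([r.error for r in records], dtype=float)
    if len(hs) < 3 or len(np.unique(hs)) < 3:
        raise ValueError("need at least 3 records at distinct h")
    if np.any(errs <= 0):
        raise ValueError("errors must be positive")
    A = np.column_stack([np.log(hs), np.ones_like(hs)])
    slope, _ = np.linalg.lstsq(A, np.log(errs), rcond=None)[0]
    return float(slope)
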