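"""Experiment drivers: the 1D conduction-velocity ladder, 2D homogeneous
and fibre-field studies, the convergence ladders and DOF tables.

Each driver returns a pandas DataFrame shaped like the corresponding
result table and can optionally write it to CSV.  The "desk" budget keeps
every study at sizes that run in minutes on one core; "full" mirrors the
original study scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import ErrorRecord, convergence_slope, cv_1d, cv_2d, error_norms
from .cell_models import CellModel, lr91_noble_form
from .dof_numbering import count_dofs
from .fibres import cubic_angle_field, laplace_dirichlet_fibres, tensor_from_fibre
from .meshing import (Mesh, build_interval_mesh, build_square_mesh,
                      build_square_with_holes_mesh)
from .simulation import (PhysicalConstants, SimulationResult, SolverConfig,
                         Stimulus, run_simulation)

__all__ = [
    "stimulus_1d",
    "stimulus_2d_bottom",
    "stimulus_2d_corner",
    "run_cv_1d",
    "CalibrationResult",
    "calibrate_beta",
    "convergence_study_1d",
    "table1_1d_cv",
    "table2_2d_homogeneous",
    "table3_cubic_fibres",
    "table4_holes",
    "fig2_ptilde1_ceiling",
    "fig45_convergence",
    "table5_dofs",
]


def stimulus_1d(depth: float = 0.05, profile_width: float = 0.0) -> Stimulus:
    """Default ramp stimulus on a 1D end segment.

    Convergence studies pass ``profile_width`` > 0 (a C-infinity spatial
    roll-off): the sharp indicator is fine for conduction velocities but
    its interpolant carries a mesh-dependent O(h) artifact that would
    floor high-order error ladders.
    """
    return Stimulus(amplitude=80.0, onset=0.0, ramp=2.0,
                    box=((0.0,), (depth,)), profile_width=profile_width)


def stimulus_2d_bottom(depth: float = 0.05) -> Stimulus:
    """Ramp stimulus in a strip along the bottom edge (planar wave)."""
    return Stimulus(amplitude=80.0, onset=0.0, ramp=2.0,
                    box=((-1e9, -1e9), (1e9, depth)))


def stimulus_2d_corner(radius: float = 0.1) -> Stimulus:
    """Ramp stimulus in a quarter-disc at the lower-left corner."""
    return Stimulus(amplitude=80.0, onset=0.0, ramp=2.0,
                    disc=((0.0, 0.0), radius))


# ---------------------------------------------------------------------------
# 1D conduction velocity and the beta calibration
# ---------------------------------------------------------------------------

def run_cv_1d(beta: float, sigma: float, h: float, p: int,
              dt: float = 0.01, length: float = 6.0, t_end: float = 400.0,
              model: CellModel | None = None, p_tilde: int = 4,
              C_m: float = 1.0):
    """6 cm strand stimulated at one end; returns (cv, t2, t4, t_end_node).

    CV uses the probes at 2 and 4 cm; t_end_node is the activation time of
    the far end of the strand.
    """
    if model is None:
        model = lr91_noble_form()
    mesh = build_interval_mesh(length, h)
    x = mesh.vertices[:, 0]
    i2 = int(np.argmin(np.abs(x - 2.0)))
    i4 = int(np.argmin(np.abs(x - 4.0)))
    iend = mesh.n_vertices - 1
    cfg = SolverConfig(p=p, p_tilde=p_tilde, dt=dt, t_end=t_end,
                       stop_when_activated=(iend,))
    res = run_simulation(mesh, model, sigma, stimulus_1d(),
                         PhysicalConstants(C_m=C_m, beta=beta), cfg)
    t2, t4 = res.activation[i2], res.activation[i4]
    if not (np.isfinite(t2) and np.isfinite(t4)):
        raise RuntimeError("wave did not reach the CV probes")
    return cv_1d(t2, t4), float(t2), float(t4), float(res.activation[iend])


@dataclass(frozen=True)
class CalibrationResult:
    beta: float
    cv: float        # achieved CV at the calibration setting, cm/s
    history: tuple


def calibrate_beta(target_cv: float = 64.52, sigma: float = 1.0,
                   h: float = 0.01, p: int = 4, dt: float = 0.01,
                   beta0: float = 1400.0, iterations: int = 2,
                   model: CellModel | None = None) -> CalibrationResult:
    """One-scalar calibration of the surface-to-volume ratio beta.

    The continuum monodomain CV scales exactly as sqrt(sigma/(beta C_m)),
    so beta_new = beta (cv/target)^2 converges in essentially one step; a
    second run verifies.
    """
    beta = beta0
    hist = []
    cv = None
    for _ in range(iterations):
        cv, *_ = run_cv_1d(beta, sigma, h, p, dt=dt, model=model)
        hist.append((beta, cv))
        beta = beta * (cv / target_cv) ** 2
    return CalibrationResult(beta=beta, cv=cv, history=tuple(hist))


def table1_1d_cv(hs=(0.05, 0.02, 0.01, 0.005), ps=(1, 2, 3, 4),
                 sigmas=(1.0, 0.2), beta: float = 1400.0,
                 dt: float = 0.01, csv_path: str | None = None) -> pd.DataFrame:
    """1D activation-time / CV grid over (h, p, sigma) — the strand study."""
    rows = []
    for h in hs:
        for p in ps:
            row = {"h": h, "p": p}
            for sigma in sigmas:
                cv, t2, t4, t_end = run_cv_1d(beta, sigma, h, p, dt=dt)
                tag = f"sigma={sigma:g}"
                row[f"activation_{tag}"] = t_end
                row[f"cv_{tag}"] = cv
            rows.append(row)
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df


# ---------------------------------------------------------------------------
# 1D convergence ladders
# ---------------------------------------------------------------------------

def _snapshot_run(mesh: Mesh, p: int, p_tilde: int, model, sigma, beta, dt,
                  t_end, stride: int) -> SimulationResult:
    cfg = SolverConfig(p=p, p_tilde=p_tilde, dt=dt, t_end=t_end,
                       snapshot_stride=stride)
    return run_simulation(mesh, model, sigma, stimulus_1d(profile_width=0.02),
                          PhysicalConstants(C_m=1.0, beta=beta), cfg)


def convergence_study_1d(hs, ps, model: CellModel, p_tilde: int = 4,
                         ref_h: float = 0.0005, ref_p: int = 4,
                         dt: float = 0.001, t_end: float = 20.0,
                         sigma: float = 0.5, beta: float = 1400.0,
                         sample_every_ms: float = 0.1,
                         reference: tuple | None = None):
    """Error ladders against a fine quartic reference on the 2 cm strand.

    Returns (records, reference) with records a dict
    (p, norm_name) -> [ErrorRecord ...]; pass ``reference`` back in to
    reuse it across studies that share the reference solution.
    """
    length = 2.0
    stride = max(1, int(round(sample_every_ms / dt)))
    if reference is None:
        mesh_r = build_interval_mesh(length, ref_h)
        res_r = _snapshot_run(mesh_r, ref_p, 4, lr91_noble_form() if model is None
                              else model, sigma, beta, dt, t_end, stride)
        reference = (mesh_r, ref_p, res_r.snapshots, res_r.times)
    mesh_r, p_r, snaps_r, times = reference
    records: dict = {}
    for p in ps:
        for h in hs:
            mesh_c = build_interval_mesh(length, h)
            res_c = _snapshot_run(mesh_c, p, p_tilde, model, sigma, beta,
                                  dt, t_end, stride)
            rec_l2, rec_h1 = error_norms(mesh_c, p, res_c.snapshots,
                                         mesh_r, p_r, snaps_r, times)
            rec_l2 = ErrorRecord(h=h, p=p, p_tilde=p_tilde, norm="Linf_L2",
                                 error=rec_l2.error, reference=rec_l2.reference)
            rec_h1 = ErrorRecord(h=h, p=p, p_tilde=p_tilde, norm="L2_H1",
                                 error=rec_h1.error, reference=rec_h1.reference)
            records.setdefault((p, "Linf_L2"), []).append(rec_l2)
            records.setdefault((p, "L2_H1"), []).append(rec_h1)
    return records, reference


def fig45_convergence(hs=(0.02, 0.01, 0.005, 0.0025), ps=(1, 2, 3),
                      beta: float = 1400.0, csv_path: str | None = None):
    """Noble-form ladders in both norms; returns (DataFrame, slopes dict)."""
    records, _ = convergence_study_1d(hs, ps, lr91_noble_form(), beta=beta)
    rows = [{"h": r.h, "p": p, "norm": norm, "error": r.error}
            for (p, norm), recs in records.items() for r in recs]
    df = pd.DataFrame(rows)
    slopes = {key: convergence_slope(recs) for key, recs in records.items()}
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df, slopes


def fig2_ptilde1_ceiling(hs=(0.01, 0.005, 0.0025), p: int = 3,
                         beta: float = 1400.0, reference=None):
    """p=3 with linear-only cell states: the quadratic error ceiling.

    Returns (slope, records); the slope should hug 2 regardless of p.
    """
    records, reference = convergence_study_1d(
        hs, (p,), lr91_noble_form(), p_tilde=1, beta=beta, reference=reference)
    return convergence_slope(records[(p, "Linf_L2")]), records, reference


# ---------------------------------------------------------------------------
# 2D drivers
# ---------------------------------------------------------------------------

def table2_2d_homogeneous(hs=(0.0444,), ps=(1, 2, 3, 4), beta: float = 1400.0,
                          dt: float = 0.01, t_end: float = 30.0, seed: int = 0,
                          n_pairs: int = 500, csv_path: str | None = None) -> pd.DataFrame:
    """Planar wave on the unit square, isotropic sigma = 1 S/m: activation
    at the top-right corner, random-pair CV, % error vs the best run."""
    rows = []
    for h in hs:
        mesh = build_square_mesh(1.0, h, seed=seed)
        corner = int(np.argmax(mesh.vertices[:, 0] + mesh.vertices[:, 1]))
        for p in ps:
            cfg = SolverConfig(p=p, p_tilde=4, dt=dt, t_end=t_end,
                               stop_when_activated=(corner,))
            res = run_simulation(mesh, lr91_noble_form(), 1.0,
                                 stimulus_2d_bottom(),
                                 PhysicalConstants(C_m=1.0, beta=beta), cfg)
            cv = cv_2d(res.activation, mesh, n_pairs=n_pairs, seed=seed)
            rows.append({"h": h, "p": p, "dofs": count_dofs(mesh, p),
                         "activation_corner": float(res.activation[corner]),
                         "cv": cv})
    df = pd.DataFrame(rows)
    best = df.iloc[df.dofs.idxmax()].cv
    df["pct_cv_error"] = 100.0 * np.abs(df.cv - best) / best
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df


_PROBE_POINTS_FIBRES = ((0.25, 0.75), (0.75, 0.75), (0.75, 0.25), (0.25, 0.25))


def table3_cubic_fibres(hs=(0.0452,), ps=(1, 2), beta: float = 1400.0,
                        dt: float = 0.01, t_end: float = 40.0, seed: int = 0,
                        cell_method: str = "rush_larsen",
                        csv_path: str | None = None) -> pd.DataFrame:
    """Anisotropic unit square with the cubic-polynomial fibre angle field
    (sigma 1 / 0.2 S/m along / across fibres), corner stimulus; activation
    at four probe points.

    Rush-Larsen gate updates by default: on the coarse anisotropic meshes
    of this study the under-resolved front can undershoot far enough to
    push the forward-Euler m-gate past its stability limit.
    """
    cond = tensor_from_fibre(cubic_angle_field(), 1.0, 0.2)
    rows = []
    for h in hs:
        mesh = build_square_mesh(1.0, h, seed=seed)
        probes = [int(np.argmin(np.linalg.norm(mesh.vertices - q, axis=1)))
                  for q in _PROBE_POINTS_FIBRES]
        for p in ps:
            cfg = SolverConfig(p=p, p_tilde=4, dt=dt, t_end=t_end,
                               cell_method=cell_method,
                               stop_when_activated=tuple(probes))
            res = run_simulation(mesh, lr91_noble_form(), cond,
                                 stimulus_2d_corner(),
                                 PhysicalConstants(C_m=1.0, beta=beta), cfg)
            row = {"h": h, "p": p, "dofs": count_dofs(mesh, p)}
            for k, v in enumerate(probes, start=1):
                row[f"activation_{k}"] = float(res.activation[v])
            rows.append(row)
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df


_PROBE_POINTS_HOLES = ((0.2, 0.8), (0.8, 0.8), (0.8, 0.2))


def table4_holes(target_h: float = 0.06, ps=(1, 2), beta: float = 1400.0,
                 dt: float = 0.01, t_end: float = 40.0, seed: int = 0,
                 cell_method: str = "rush_larsen",
                 csv_path: str | None = None) -> pd.DataFrame:
    """Unit square with two circular holes, Laplace-Dirichlet fibres
    (sigma 1 / 0.2 S/m), bottom-edge stimulus; activation at three probes.

    Rush-Larsen gate updates by default, as in :func:`table3_cubic_fibres`.
    """
    mesh = build_square_with_holes_mesh(1.0, target_h=target_h, seed=seed)
    field, _ = laplace_dirichlet_fibres(mesh, "left", "right")
    cond = tensor_from_fibre(field, 1.0, 0.2)
    probes = [int(np.argmin(np.linalg.norm(mesh.vertices - q, axis=1)))
              for q in _PROBE_POINTS_HOLES]
    rows = []
    for p in ps:
        cfg = SolverConfig(p=p, p_tilde=4, dt=dt, t_end=t_end,
                           cell_method=cell_method,
                           stop_when_activated=tuple(probes))
        res = run_simulation(mesh, lr91_noble_form(), cond,
                             stimulus_2d_bottom(),
                             PhysicalConstants(C_m=1.0, beta=beta), cfg)
        row = {"max_h": float(mesh.element_diameters().max()), "p": p,
               "dofs": count_dofs(mesh, p)}
        for k, v in enumerate(probes, start=1):
            row[f"activation_{k}"] = float(res.activation[v])
        rows.append(row)
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df


def table5_dofs(hs=(0.0444, 0.0222), ps=(1, 2, 3, 4), seed: int = 0,
                with_holes: bool = False,
                csv_path: str | None = None) -> pd.DataFrame:
    """DOF counts N = V + (p-1)E + i(p)T on generated mesh ladders."""
    rows = []
    for level, h in enumerate(hs):
        mesh = (build_square_with_holes_mesh(1.0, target_h=h, seed=seed)
                if with_holes else build_square_mesh(1.0, h, seed=seed))
        for p in ps:
            rows.append({"level": level, "h": h, "p": p,
                         "V": mesh.n_vertices, "E": mesh.n_edges,
                         "T": mesh.n_elements, "dofs": count_dofs(mesh, p)})
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df
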