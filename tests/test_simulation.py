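import numpy as np
import pytest

from hpmono.assembly import assemble_mass, assemble_stiffness
from hpmono.cell_models import lr91_noble_form
from hpmono.dof_numbering import DofMap
from hpmono.drivers import stimulus_1d
from hpmono.meshing import build_interval_mesh
from hpmono.simulation import (IluLinearBlockPreconditioner, PhysicalConstants,
                               SolverConfig, Stimulus, ilu_linear_block_pcg,
                               make_stepper, run_simulation, system_matrix)


from _oracles import CONST, textbook_p1_monodomain_step, zero_model


def test_system_matrix_limits_and_spd():
    mesh = build_interval_mesh(1.0, 0.1)
    dm = DofMap(mesh, 3)
    M = assemble_mass(mesh, dm)
    A = assemble_stiffness(mesh, dm, 10.0)
    K = system_matrix(M, A, 1e-12, CONST)
    assert abs(K - M).max() < 1e-10  # dt -> 0 limit
    K = system_matrix(M, A, 0.01, CONST)
    np.linalg.cholesky(K.toarray())  # SPD
    # constant kernel of A: K c = M c
    c = np.zeros(dm.n_dofs)
    c[: mesh.n_vertices] = 1.0
    np.testing.assert_allclose(K @ c, M @ c, atol=1e-14)


def test_uniform_state_is_a_fixed_point():
    """Zero current + Neumann walls: a spatially uniform u never moves."""
    mesh = build_interval_mesh(1.0, 0.05)
    cfg = SolverConfig(p=3, p_tilde=4, dt=0.05, t_end=1.0)
    st = make_stepper(mesh, zero_model(), 1.0, None, CONST, cfg)
    u, w = st.initial_state()
    for k in range(3):
        u2, w, _ = st.step(u, w, 0.0)
        assert np.abs(u2 - u).max() <= 1e-12
        u = u2


def test_pure_diffusion_matches_backward_euler_amplification():
    """u0 = cos(pi x/L) decays by (1 + dt D (pi/L)^2)^-1 per step."""
    mesh = build_interval_mesh(1.0, 0.002)
    cfg = SolverConfig(p=1, p_tilde=1, dt=0.01, t_end=0.1)
    st = make_stepper(mesh, zero_model(), 1.0, None, CONST, cfg)
    u = np.cos(np.pi * mesh.vertices[:, 0])
    w = np.zeros((1, st.ops.nodal.n_nodes))
    D = 10.0 / (CONST.beta * CONST.C_m)  # sigma = 1 S/m = 10 mS/cm
    predicted = 1.0 / (1.0 + cfg.dt * D * np.pi ** 2)
    for _ in range(5):
        u, w, _ = st.step(u, w, 0.0)
    x = mesh.vertices[:, 0]
    interior = (x > 0.2) & (x < 0.8) & (np.abs(x - 0.5) > 0.01)  # avoid the cosine root
    ratio = u[: mesh.n_vertices][interior] / np.cos(np.pi * x[interior])
    np.testing.assert_allclose(ratio, predicted ** 5, rtol=2e-4)


def test_weighted_mean_conserved_without_current():
    """1^T M u is invariant when I = 0 (Neumann + constant kernel)."""
    mesh = build_interval_mesh(1.0, 0.05)
    cfg = SolverConfig(p=4, p_tilde=4, dt=0.05, t_end=1.0, cg_tol=1e-13)
    st = make_stepper(mesh, zero_model(), 1.0, None, CONST, cfg)
    rng = np.random.default_rng(3)
    u = rng.normal(size=st.ops.dofmap.n_dofs)
    w = np.zeros((1, st.ops.nodal.n_nodes))
    ones = np.zeros(st.ops.dofmap.n_dofs)
    ones[: mesh.n_vertices] = 1.0
    m0 = ones @ (st.ops.M @ u)
    for k in range(10):
        u, w, _ = st.step(u, w, 0.0)
    m1 = ones @ (st.ops.M @ u)
    assert abs(m1 - m0) <= 1e-10 * max(1.0, abs(m0))


def test_p1_scheme_equals_textbook_stepper():
    """At p = p_tilde = 1 the full machinery reduces to the classic linear
    FEM monodomain scheme, step for step, to 1e-10."""
    mesh = build_interval_mesh(1.0, 0.1)  # 10 elements
    model = lr91_noble_form()
    stim = Stimulus(amplitude=80.0, ramp=2.0, box=((0.0,), (0.15,)))
    cfg = SolverConfig(p=1, p_tilde=1, dt=0.01, t_end=1.0, cg_tol=1e-14)
    st = make_stepper(mesh, model, 1.0, stim, CONST, cfg)
    u, w = st.initial_state()
    u_ref, w_ref = u[: mesh.n_vertices].copy(), w.copy()
    for k in range(50):
        t = k * cfg.dt
        u, w, _ = st.step(u, w, t)
        u_ref, w_ref = textbook_p1_monodomain_step(
            mesh, model, 10.0, stim, CONST, cfg.dt, u_ref, w_ref, t)
        assert np.abs(u - u_ref).max() <= 1e-10
        assert np.abs(w - w_ref).max() <= 1e-10


def test_ilu_pcg_iteration_counts():
    mesh = build_interval_mesh(2.0, 0.01)  # 201 vertices
    const = PhysicalConstants(C_m=1.0, beta=1400.0)
    rng = np.random.default_rng(0)
    counts = {}
    for p in (1, 4):
        dm = DofMap(mesh, p)
        M = assemble_mass(mesh, dm)
        A = assemble_stiffness(mesh, dm, 10.0)
        K = system_matrix(M, A, 0.01, const)
        pc = IluLinearBlockPreconditioner(K, mesh.n_vertices)
        rhs = K @ rng.normal(size=dm.n_dofs)
        x, n_iter = ilu_linear_block_pcg(K, rhs, pc, tol=1e-8)
        assert np.abs(K @ x - rhs).max() <= 1e-6 * np.abs(rhs).max()
        counts[p] = n_iter
    assert counts[1] <= 30
    # the higher-order system stays cheap: within 4x the linear cost (with
    # a small floor, since the p=1 ILU is essentially exact)
    assert counts[4] <= 4 * max(counts[1], 4)


def test_subthreshold_stimulus_does_not_propagate():
    mesh = build_interval_mesh(1.0, 0.02)
    stim = Stimulus(amplitude=2.0, ramp=2.0, box=((0.0,), (0.05,)))
    cfg = SolverConfig(p=2, p_tilde=4, dt=0.01, t_end=10.0)
    with pytest.warns(RuntimeWarning, match="no activation"):
        res = run_simulation(mesh, lr91_noble_form(), 1.0, stim, CONST, cfg)
    outside = mesh.vertices[:, 0] > 0.06
    assert np.isnan(res.activation[outside]).all()


def test_activation_monotone_along_strand(noble_model):
    """Wave causality: activation time is non-decreasing with distance
    from the stimulated end."""
    mesh = build_interval_mesh(2.0, 0.02)
    cfg = SolverConfig(p=4, p_tilde=4, dt=0.01, t_end=30.0,
                       stop_when_activated=(mesh.n_vertices - 1,))
    res = run_simulation(mesh, noble_model, 1.0, stimulus_1d(), CONST, cfg)
    act = res.activation
    assert np.isfinite(act).all()
    x = mesh.vertices[:, 0]
    inner = x > 0.1  # outside the stimulated patch
    assert (np.diff(act[inner]) >= -1e-9).all()


def test_cv_scales_as_sqrt_sigma(noble_model):
    """Doubling sigma multiplies CV by sqrt(2) (diffusion scaling law)."""
    cvs = {}
    for sigma in (0.5, 1.0):
        mesh = build_interval_mesh(2.0, 0.01)
        x = mesh.vertices[:, 0]
        ia = int(np.argmin(np.abs(x - 0.5)))
        ib = int(np.argmin(np.abs(x - 1.5)))
        cfg = SolverConfig(p=3, p_tilde=4, dt=0.01, t_end=40.0,
                           stop_when_activated=(mesh.n_vertices - 1,))
        res = run_simulation(mesh, noble_model, sigma, stimulus_1d(), CONST, cfg)
        cvs[sigma] = 1.0 / (res.activation[ib] - res.activation[ia])
    assert cvs[1.0] / cvs[0.5] == pytest.approx(np.sqrt(2.0), rel=0.03)


def test_time_self_convergence_first_order(noble_model):
    """Halving dt changes the final field by O(dt): the dt vs dt/2
    discrepancy shrinks by about half again at dt/2 vs dt/4."""
    mesh = build_interval_mesh(0.5, 0.01)
    finals = {}
    for dt in (0.01, 0.005, 0.0025):
        cfg = SolverConfig(p=2, p_tilde=4, dt=dt, t_end=4.0)
        res = run_simulation(mesh, noble_model, 1.0, stimulus_1d(), CONST, cfg)
        finals[dt] = res.final_u[: mesh.n_vertices]
    d1 = np.abs(finals[0.01] - finals[0.005]).max()
    d2 = np.abs(finals[0.005] - finals[0.0025]).max()
    assert 0.3 <= d1 / d2 <= 3.5  # ratio ~2 for a first-order scheme
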