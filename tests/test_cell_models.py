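import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hpmono.cell_models import (fitzhugh_nagumo, integrate_cell,
                                scan_rate_discontinuities, step_states)


def reference_cell_solution(model, t_end, y0=None, rtol=1e-9):
    """Independent oracle: adaptive-step integration of the cell ODEs."""
    def rhs(t, y):
        u = np.array([y[0]])
        w = y[1:].reshape(model.m, 1)
        return np.concatenate([[model.I_ionic(u, w)[0]], model.g(u, w)[:, 0]])
    if y0 is None:
        y0 = np.concatenate([[model.u0], model.w0])
    return solve_ivp(rhs, [0.0, t_end], y0, method="LSODA", rtol=rtol,
                     atol=1e-12)


def test_quiescent_cell_stays_at_rest(noble_model):
    """With no stimulus the frozen resting state drifts < 1 mV in 500 ms,
    in both the forward-Euler loop and an adaptive ODE oracle."""
    sol = reference_cell_solution(noble_model, 500.0)
    assert abs(sol.y[0, -1] - noble_model.u0) < 1.0
    t, u, _ = integrate_cell(noble_model, 0.05, 500.0, record_every=200,
                             method="rush_larsen")
    assert np.abs(u - noble_model.u0).max() < 1.0
    assert abs(noble_model.u0 + 84) < 2.0  # resting potential ~ -84 mV


def test_standard_rates_jump_at_minus40(standard_model):
    """The published piecewise h-gate rates are discontinuous at -40 mV."""
    eps = 1e-9
    a_lo = standard_model.rates["alpha_h"](np.array([-40.0 - eps]))[0]
    a_hi = standard_model.rates["alpha_h"](np.array([-40.0 + eps]))[0]
    assert abs(a_lo - a_hi) > 1e-5
    report = scan_rate_discontinuities(standard_model)
    assert report.entries, "scan must flag the -40 mV switch"
    assert any(abs(v + 40.0) < 0.05 for v in report.switch_voltages)


def test_noble_form_is_continuous_and_matches_tails(noble_model, standard_model):
    assert not scan_rate_discontinuities(noble_model).entries
    V = np.array([-85.0, -60.0, -25.0, 0.0, 40.0])  # > 10 widths from -40
    for name in noble_model.rates:
        a = noble_model.rates[name](V)
        b = standard_model.rates[name](V)
        nz = np.abs(b) > 0
        assert np.all(np.abs(a[nz] - b[nz]) <= 1e-6 * np.abs(b[nz]))


def test_noble_vs_standard_ap_difference_is_minor(noble_model, standard_model):
    """The continuity repair barely changes the single-cell AP (<= 5% of
    the AP amplitude pointwise)."""
    stim = lambda t: 40.0 if t <= 2.0 else 0.0
    _, u_n, _ = integrate_cell(noble_model, 0.01, 400.0, stimulus=stim,
                               record_every=10)
    _, u_s, _ = integrate_cell(standard_model, 0.01, 400.0, stimulus=stim,
                               record_every=10)
    amplitude = u_n.max() - u_n.min()
    assert amplitude > 100.0  # a real action potential fired
    assert np.abs(u_n - u_s).max() <= 0.05 * amplitude


def test_gates_at_steady_state_have_zero_kinetics(noble_model):
    u = np.array([-60.0, -20.0, 10.0])
    alpha, beta = noble_model.gate_alpha_beta(u)
    w = noble_model.initial_states(3)
    w[:6] = alpha / (alpha + beta)
    dw = noble_model.g(u, w)
    assert np.abs(dw[:6]).max() < 1e-12


def test_fitzhugh_nagumo_equilibrium_and_excursion():
    fhn = fitzhugh_nagumo()
    # rest (the cubic nullcline intersection) is an equilibrium
    u = np.array([fhn.u0])
    w = fhn.w0[:, None]
    assert abs(fhn.I_ionic(u, w)[0]) < 1e-12
    assert abs(fhn.g(u, w)[0, 0]) < 1e-12
    assert not scan_rate_discontinuities(fhn).entries
    # suprathreshold kick: large excursion, then return toward rest
    sol = reference_cell_solution(fhn, 600.0,
                                  y0=np.array([fhn.u0 + 30.0, 0.0]))
    assert sol.y[0].max() > fhn.u0 + 60.0
    assert abs(sol.y[0, -1] - fhn.u0) < 2.0
    # eps -> 0: recovery variable frozen over short horizons
    slow = fitzhugh_nagumo(eps=1e-9)
    sol2 = reference_cell_solution(slow, 5.0,
                                   y0=np.array([slow.u0 + 30.0, 0.0]))
    assert abs(sol2.y[1, -1]) < 1e-6


def test_step_states_consistency_order(noble_model):
    """w(dt) - w(0) = dt g + O(dt^2): Richardson quotient ~ 2 for FE."""
    u = np.linspace(-80.0, 20.0, 11)
    w = noble_model.initial_states(11)
    g = noble_model.g(u, w)
    e1 = step_states(noble_model, u, w, 1e-4) - (w + 1e-4 * g)
    e2 = step_states(noble_model, u, w, 2e-4) - (w + 2e-4 * g)
    assert np.abs(e2).max() <= 4.5 * np.abs(e1).max() + 1e-14


def test_rush_larsen_gates_bounded_any_dt(noble_model, rng):
    u = rng.uniform(-90.0, 40.0, 64)
    w = noble_model.initial_states(64)
    w[:6] = rng.uniform(0.0, 1.0, (6, 64))
    for dt in (0.01, 1.0, 50.0):
        out = step_states(noble_model, u, w, dt, method="rush_larsen")
        assert out[:6].min() >= 0.0 and out[:6].max() <= 1.0


def test_step_states_pure_and_validates(noble_model):
    u = np.array([-30.0, -30.0])
    w = noble_model.initial_states(2)
    out = step_states(noble_model, u, w, 0.01)
    np.testing.assert_array_equal(out[:, 0], out[:, 1])
    with pytest.raises(ValueError):
        step_states(noble_model, u, w, -0.1)
    with pytest.raises(ValueError):
        step_states(noble_model, u, w[:3], 0.1)


def test_fused_update_matches_generic_path(noble_model, rng):
    """The fused step-and-current shortcut is algebraically identical to
    step_states followed by I_ionic."""
    u = rng.uniform(-90.0, 40.0, 257)
    w = noble_model.initial_states(257) * rng.uniform(0.95, 1.05, (7, 257))
    for method in ("fe", "rush_larsen"):
        w_ref = step_states(noble_model, u, w, 0.005, method=method)
        i_ref = noble_model.I_ionic(u, w_ref)
        w_fus, i_fus = noble_model.step_and_current(u, w, 0.005, method=method)
        np.testing.assert_allclose(w_fus, w_ref, rtol=0, atol=1e-14)
        np.testing.assert_allclose(i_fus, i_ref, rtol=1e-12)


def test_negative_calcium_rejected(noble_model):
    u = np.array([0.0])
    w = noble_model.initial_states(1)
    w[6] = -1e-5
    with pytest.raises(ValueError, match="Ca"):
        noble_model.I_ionic(u, w)
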