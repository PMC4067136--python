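"""Ionic cell models: the Luo-Rudy 1991 (LR91) ventricular model, a
continuous "Noble-form" variant of it, and FitzHugh-Nagumo.

Units: potential mV, time ms, currents uA/cm^2, capacitance uF/cm^2,
concentrations mM.  ``I_ionic`` returns the current with the sign
convention that depolarising current is positive on the right-hand side of
C_m du/dt = ... + I_ionic + I_stim; i.e. it is minus the usual outward
membrane current sum.

The original LR91 transition rates for the fast-sodium inactivation gates h
and j are defined piecewise with a switch at -40 mV and are discontinuous
there; this clips the spatial convergence order of high-degree schemes.
``lr91_noble_form`` replaces each piecewise rate by a logistic blend of the
two analytic branches centred on -40 mV, which restores continuity while
matching both branches away from the switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "CellModel",
    "RateDiscontinuityReport",
    "lr91_standard",
    "lr91_noble_form",
    "fitzhugh_nagumo",
    "scan_rate_discontinuities",
    "step_states",
    "integrate_cell",
]


@dataclass
class CellModel:
    """An ionic model: states w, kinetics g(u, w) and current I_ionic(u, w)."""

    name: str
    state_names: tuple
    u0: float                      # resting potential, mV
    w0: np.ndarray                 # resting states
    I_ionic: Callable              # (u, w) -> uA/cm^2, depolarising positive
    g: Callable                    # (u, w) -> dw/dt (per ms)
    rates: dict = field(default_factory=dict)   # name -> rate(V) for scanning
    gate_alpha_beta: Callable | None = None     # (u) -> (alpha, beta) arrays
    n_gates: int = 0
    #: optional fused (w_next, I_ionic) update sharing the u-only terms;
    #: algebraically identical to step_states + I_ionic, just faster
    step_and_current: Callable | None = None

    @property
    def m(self) -> int:
        return len(self.state_names)

    def initial_states(self, n_points: int) -> np.ndarray:
        return np.repeat(self.w0[:, None], n_points, axis=1)


# ---------------------------------------------------------------------------
# LR91
# ---------------------------------------------------------------------------

# extracellular / intracellular concentrations (mM) and derived potentials
_KO, _KI = 5.4, 145.0
_NAO, _NAI = 140.0, 18.0
_RTF = 8314.472 * 310.0 / 96485.34  # mV
_E_NA = _RTF * np.log(_NAO / _NAI)
_PR_NAK = 0.01833
_E_K = _RTF * np.log((_KO + _PR_NAK * _NAO) / (_KI + _PR_NAK * _NAI))
_E_K1 = _RTF * np.log(_KO / _KI)
_G_K = 0.282 * np.sqrt(_KO / 5.4)
_G_K1 = 0.6047 * np.sqrt(_KO / 5.4)

# resting state of the continuous (Noble-form) model, frozen from a long
# unstimulated relaxation with an adaptive ODE integrator
_LR91_U0 = -84.55157904008966
_LR91_W0 = np.array([
    1.665214e-03,   # m
    9.833192e-01,   # h
    9.895322e-01,   # j
    2.976294e-03,   # d
    9.999813e-01,   # f
    5.640979e-03,   # X
    1.783354e-04,   # Cai (mM)
])

_GATE_NAMES = ("m", "h", "j", "d", "f", "X")


def _safe_exp(x):
    # only overflow needs guarding; underflow quietly reaches 0
    return np.exp(np.minimum(x, 700.0))


# --- transition rates; each takes V (mV, array ok) and returns 1/ms -------

def _alpha_m(V):
    num = 0.32 * (V + 47.13)
    den = 1.0 - _safe_exp(-0.1 * (V + 47.13))
    out = np.where(np.abs(V + 47.13) < 1e-7, 3.2, num / np.where(den == 0, 1.0, den))
    return out


def _beta_m(V):
    return 0.08 * _safe_exp(-V / 11.0)


def _alpha_h_lo(V):
    return 0.135 * _safe_exp(-(80.0 + V) / 6.8)


def _alpha_h_hi(V):
    return np.zeros_like(np.asarray(V, dtype=float))


def _beta_h_lo(V):
    return 3.56 * _safe_exp(0.079 * V) + 3.1e5 * _safe_exp(0.35 * V)


def _beta_h_hi(V):
    return 1.0 / (0.13 * (1.0 + _safe_exp(-(V + 10.66) / 11.1)))


def _alpha_j_lo(V):
    return ((-1.2714e5 * _safe_exp(0.2444 * V) - 3.474e-5 * _safe_exp(-0.04391 * V))
            * (V + 37.78) / (1.0 + _safe_exp(0.311 * (V + 79.23))))


def _alpha_j_hi(V):
    return np.zeros_like(np.asarray(V, dtype=float))


def _beta_j_lo(V):
    return 0.1212 * _safe_exp(-0.01052 * V) / (1.0 + _safe_exp(-0.1378 * (V + 40.14)))


def _beta_j_hi(V):
    return 0.3 * _safe_exp(-2.535e-7 * V) / (1.0 + _safe_exp(-0.1 * (V + 32.0)))


def _alpha_d(V):
    return 0.095 * _safe_exp(-0.01 * (V - 5.0)) / (1.0 + _safe_exp(-0.072 * (V - 5.0)))


def _beta_d(V):
    return 0.07 * _safe_exp(-0.017 * (V + 44.0)) / (1.0 + _safe_exp(0.05 * (V + 44.0)))


def _alpha_f(V):
    return 0.012 * _safe_exp(-0.008 * (V + 28.0)) / (1.0 + _safe_exp(0.15 * (V + 28.0)))


def _beta_f(V):
    return 0.0065 * _safe_exp(-0.02 * (V + 30.0)) / (1.0 + _safe_exp(-0.2 * (V + 30.0)))


def _alpha_X(V):
    return 0.0005 * _safe_exp(0.083 * (V + 50.0)) / (1.0 + _safe_exp(0.057 * (V + 50.0)))


def _beta_X(V):
    return 0.0013 * _safe_exp(-0.06 * (V + 20.0)) / (1.0 + _safe_exp(-0.04 * (V + 20.0)))


def _switch_standard(lo, hi):
    """Original LR91 piecewise rate: lo branch below -40 mV, hi above."""
    def rate(V):
        V = np.asarray(V, dtype=float)
        return np.where(V < -40.0, lo(V), hi(V))
    return rate


def _switch_logistic(lo, hi, width_mV: float):
    """Continuous Noble-form repair: logistic blend centred at -40 mV."""
    k = width_mV / 4.0

    def rate(V):
        V = np.asarray(V, dtype=float)
        s = 1.0 / (1.0 + _safe_exp(-(V + 40.0) / k))
        return (1.0 - s) * lo(V) + s * hi(V)
    return rate


def _xi_factor(V):
    """Time-independent rectification factor of the K current."""
    V = np.asarray(V, dtype=float)
    d = V + 77.0
    num = _safe_exp(0.04 * (V + 77.0)) - 1.0
    den = d * _safe_exp(0.04 * (V + 35.0))
    lim = 0.04 / _safe_exp(0.04 * (V + 35.0))
    core = np.where(np.abs(d) < 1e-6, lim, num / np.where(d == 0, 1.0, den))
    return np.where(V > -100.0, 2.837 * core, 1.0)


def _k1_inf(V):
    a = 1.02 / (1.0 + _safe_exp(0.2385 * (V - _E_K1 - 59.215)))
    b = ((0.49124 * _safe_exp(0.08032 * (V - _E_K1 + 5.476))
          + _safe_exp(0.06175 * (V - _E_K1 - 594.31)))
         / (1.0 + _safe_exp(-0.5143 * (V - _E_K1 + 4.753))))
    return a / (a + b)


def _build_lr91(name: str, switch) -> CellModel:
    rates = {
        "alpha_m": _alpha_m, "beta_m": _beta_m,
        "alpha_h": switch(_alpha_h_lo, _alpha_h_hi),
        "beta_h": switch(_beta_h_lo, _beta_h_hi),
        "alpha_j": switch(_alpha_j_lo, _alpha_j_hi),
        "beta_j": switch(_beta_j_lo, _beta_j_hi),
        "alpha_d": _alpha_d, "beta_d": _beta_d,
        "alpha_f": _alpha_f, "beta_f": _beta_f,
        "alpha_X": _alpha_X, "beta_X": _beta_X,
    }
    alist = [rates[f"alpha_{gname}"] for gname in _GATE_NAMES]
    blist = [rates[f"beta_{gname}"] for gname in _GATE_NAMES]

    def gate_alpha_beta(u):
        u = np.asarray(u, dtype=float)
        alpha = np.stack([f(u) for f in alist])
        beta = np.stack([f(u) for f in blist])
        return alpha, beta

    def currents(u, w):
        u = np.asarray(u, dtype=float)
        mg, h, j, d, f, X, cai = w
        if np.any(cai <= 0):
            raise ValueError("non-positive [Ca2+]i in slow-inward reversal")
        i_na = 23.0 * mg ** 3 * h * j * (u - _E_NA)
        e_si = 7.7 - 13.0287 * np.log(cai)
        i_si = 0.09 * d * f * (u - e_si)
        i_k = _G_K * X * _xi_factor(u) * (u - _E_K)
        i_k1 = _G_K1 * _k1_inf(u) * (u - _E_K1)
        i_kp = 0.0183 / (1.0 + _safe_exp((7.488 - u) / 5.98)) * (u - _E_K1)
        i_b = 0.03921 * (u + 59.87)
        return i_na, i_si, i_k, i_k1, i_kp, i_b

    def I_ionic(u, w):
        i_na, i_si, i_k, i_k1, i_kp, i_b = currents(u, w)
        return -(i_na + i_si + i_k + i_k1 + i_kp + i_b)

    def g(u, w):
        u = np.asarray(u, dtype=float)
        alpha, beta = gate_alpha_beta(u)
        gates = w[:6]
        dw = np.empty_like(np.broadcast_arrays(w, np.zeros((7,) + u.shape))[0])
        dw[:6] = alpha * (1.0 - gates) - beta * gates
        _, i_si, *_ = currents(u, w)
        dw[6] = -1e-4 * i_si + 0.07 * (1e-4 - w[6])
        return dw

    def step_and_current(u, w, dt, method="fe", use_new_states=True):
        """Fused state update + ionic current, sharing u-only factors."""
        u = np.asarray(u, dtype=float)
        alpha, beta = gate_alpha_beta(u)
        # u-only current components (K currents and background)
        i_k_per_X = _G_K * _xi_factor(u) * (u - _E_K)  # gate X applied below
        i_k1 = _G_K1 * _k1_inf(u) * (u - _E_K1)
        i_kp = 0.0183 / (1.0 + _safe_exp((7.488 - u) / 5.98)) * (u - _E_K1)
        i_b = 0.03921 * (u + 59.87)
        cai = w[6]
        if np.any(cai <= 0):
            raise ValueError("non-positive [Ca2+]i in slow-inward reversal")
        i_si_old = 0.09 * w[3] * w[4] * (u - (7.7 - 13.0287 * np.log(cai)))
        w_new = np.empty_like(w)
        gates = w[:6]
        if method == "fe":
            w_new[:6] = gates + dt * (alpha * (1.0 - gates) - beta * gates)
        elif method == "rush_larsen":
            tau_inv = alpha + beta
            winf = alpha / np.where(tau_inv == 0, 1.0, tau_inv)
            w_new[:6] = winf + (gates - winf) * np.exp(-dt * tau_inv)
        else:
            raise ValueError(f"unknown method {method!r}")
        w_new[6] = cai + dt * (-1e-4 * i_si_old + 0.07 * (1e-4 - cai))
        wc = w_new if use_new_states else w
        i_na = 23.0 * wc[0] ** 3 * wc[1] * wc[2] * (u - _E_NA)
        i_si = 0.09 * wc[3] * wc[4] * (u - (7.7 - 13.0287 * np.log(wc[6])))
        i_k = i_k_per_X * wc[5]
        total = -(i_na + i_si + i_k + i_k1 + i_kp + i_b)
        if not np.all(np.isfinite(w_new)):
            idx = np.argwhere(~np.isfinite(w_new))[0]
            raise FloatingPointError(f"cell state blow-up at point index {tuple(idx)}")
        return w_new, total

    return CellModel(name=name, state_names=_GATE_NAMES + ("Cai",),
                     u0=_LR91_U0, w0=_LR91_W0.copy(),
                     I_ionic=I_ionic, g=g, rates=rates,
                     gate_alpha_beta=gate_alpha_beta, n_gates=6,
                     step_and_current=step_and_current)


def lr91_standard() -> CellModel:
    """The published LR91 model with its piecewise h/j rates (-40 mV switch)."""
    return _build_lr91("lr91", _switch_standard)


def lr91_noble_form(blend_width: float = 1.0) -> CellModel:
    """LR91 with continuous (logistically blended) h/j rates.

    ``blend_width`` (mV) sets the voltage scale of the transition; the
    blend matches both original branches to relative 1e-6 once more than
    ~10 widths from -40 mV.
    """
    if blend_width <= 0:
        raise ValueError("blend_width must be positive")
    return _build_lr91("lr91-noble",
                       lambda lo, hi: _switch_logistic(lo, hi, blend_width))


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo
# ---------------------------------------------------------------------------

def fitzhugh_nagumo(a: float = 0.13, b: float = 2.5, eps: float = 0.008,
                    amplitude: float = 100.0, u_rest: float = -85.0) -> CellModel:
    """Two-variable FitzHugh-Nagumo model rescaled to a mV-like range.

    dv/dt = v(v-a)(1-v) - w,   dw/dt = eps (v - b w),  u = u_rest + amplitude*v.
    All rates are polynomial, hence free of discontinuities.
    """
    def to_v(u):
        return (np.asarray(u, dtype=float) - u_rest) / amplitude

    def I_ionic(u, w):
        v = to_v(u)
        return amplitude * (v * (v - a) * (1.0 - v) - w[0])

    def g(u, w):
        v = to_v(u)
        return np.array([eps * (v - b * w[0])])

    return CellModel(name="fhn", state_names=("w",), u0=u_rest,
                     w0=np.array([0.0]), I_ionic=I_ionic, g=g,
                     rates={"reaction": lambda V: to_v(V) * (to_v(V) - a) * (1.0 - to_v(V))})


# ---------------------------------------------------------------------------
# discontinuity scan
# ---------------------------------------------------------------------------

@dataclass
class RateDiscontinuityReport:
    """Jumps detected in the voltage-dependent transition rates."""

    entries: list  # (rate_name, switch_V, left_limit, right_limit, jump)

    def __bool__(self):
        return bool(self.entries)

    @property
    def switch_voltages(self):
        return [e[1] for e in self.entries]


def scan_rate_discontinuities(model: CellModel,
                              v_range=(-90.0, 40.0),
                              step: float = 0.05) -> RateDiscontinuityReport:
    """Scan every rate function on a grid and flag jumps that exceed 100x
    the local grid-Lipschitz estimate; locations are refined by bisection."""
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = v_range
    V = np.arange(lo, hi + step / 2, step)
    entries = []
    for name, rate in model.rates.items():
        vals = np.asarray(rate(V), dtype=float)
        d = np.abs(np.diff(vals))
        scale = np.maximum(np.abs(vals[:-1]), np.abs(vals[1:]))
        for i in range(1, len(d) - 1):
            lip = max(d[i - 1], d[i + 1])
            if d[i] > 100.0 * lip + 1e-12 * scale[i] and d[i] > 1e-14:
                a, b = V[i], V[i + 1]
                for _ in range(60):  # bisection to locate the switch
                    mid = 0.5 * (a + b)
                    if abs(float(rate(np.array([mid]))[0]) - vals[i]) \
                            > abs(float(rate(np.array([mid]))[0]) - vals[i + 1]):
                        b = mid
                    else:
                        a = mid
                left = float(rate(np.array([a]))[0])
                right = float(rate(np.array([b]))[0])
                entries.append((name, 0.5 * (a + b), left, right,
                                abs(right - left)))
    return RateDiscontinuityReport(entries=entries)


# ---------------------------------------------------------------------------
# state integration (pointwise, no spatial coupling)
# ---------------------------------------------------------------------------

def step_states(model: CellModel, u_values: np.ndarray, w_values: np.ndarray,
                dt: float, method: str = "fe") -> np.ndarray:
    """Advance the cell states at every point by one step of ``dt``.

    "fe" is plain forward Euler; "rush_larsen" uses the exponential gate
    update (a convex combination, so gates stay in [0, 1] for any dt) with
    forward Euler on the non-gate states.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u_values, dtype=float)
    w = np.asarray(w_values, dtype=float)
    if w.shape[0] != model.m or w.shape[1:] != u.shape:
        raise ValueError("state array incongruent with u values")
    if method == "fe" or model.gate_alpha_beta is None:
        out = w + dt * model.g(u, w)
    elif method == "rush_larsen":
        alpha, beta = model.gate_alpha_beta(u)
        tau_inv = alpha + beta
        winf = alpha / np.where(tau_inv == 0, 1.0, tau_inv)
        decay = np.exp(-dt * tau_inv)
        out = w.copy()
        ng = model.n_gates
        out[:ng] = winf + (w[:ng] - winf) * decay
        rest = model.g(u, w)[ng:]
        out[ng:] = w[ng:] + dt * rest
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(out)):
        idx = np.argwhere(~np.isfinite(out))[0]
        raise FloatingPointError(f"cell state blow-up at point index {tuple(idx)}")
    return out


def integrate_cell(model: CellModel, dt: float, t_end: float,
                   stimulus: Callable | None = None, method: str = "fe",
                   record_every: int = 1):
    """Integrate a single cell; returns (times, u trace, state traces).

    ``stimulus`` maps time (ms) to a depolarising current (uA/cm^2);
    membrane capacitance is 1 uF/cm^2.
    """
    n = int(round(t_end / dt))
    u = np.array([model.u0])
    w = model.w0[:, None].copy()
    times, us, ws = [0.0], [model.u0], [model.w0.copy()]
    for i in range(n):
        t = i * dt
        if model.step_and_current is not None:
            w, ion = model.step_and_current(u, w, dt, method=method)
        else:
            w = step_states(model, u, w, dt, method=method)
            ion = model.I_ionic(u, w)
        istim = stimulus(t + dt) if stimulus else 0.0
        u = u + dt * (ion + istim)
        if (i + 1) % record_every == 0:
            times.append((i + 1) * dt)
            us.append(float(u[0]))
            ws.append(w[:, 0].copy())
    return np.array(times), np.array(us), np.array(ws)
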