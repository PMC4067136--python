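"""Shared independent oracles for the simulation tests."""

import numpy as np

from hpmono.cell_models import CellModel, step_states
from hpmono.simulation import PhysicalConstants

CONST = PhysicalConstants(C_m=1.0, beta=1400.0)


def zero_model(u0=1.0):
    """A current-free cell model: isolates the diffusion operator."""
    return CellModel(name="zero", state_names=("w",), u0=u0,
                     w0=np.array([0.0]), I_ionic=lambda u, w: 0.0 * u,
                     g=lambda u, w: np.zeros((1,) + u.shape))


def textbook_p1_monodomain_step(mesh, model, sigma_ms_cm, stim, const, dt,
                                u, w, t):
    """Independent oracle: dense linear-FEM monodomain stepper with hat
    functions, nodal currents and backward-Euler diffusion."""
    x = mesh.vertices[:, 0]
    n = len(x)
    h = np.diff(x)
    M = np.zeros((n, n))
    A = np.zeros((n, n))
    for e in range(n - 1):
        he = h[e]
        M[e:e + 2, e:e + 2] += he / 6 * np.array([[2, 1], [1, 2]])
        A[e:e + 2, e:e + 2] += sigma_ms_cm / he * np.array([[1, -1], [-1, 1]])
    w_new = step_states(model, u, w, dt)
    I = model.I_ionic(u, w_new)
    if stim is not None:
        I = I + stim.amplitude_at(t + dt) * stim.mask(mesh.vertices)
    K = M + dt / (const.beta * const.C_m) * A
    rhs = M @ u + (dt / const.C_m) * (M @ I)
    return np.linalg.solve(K, rhs), w_new
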