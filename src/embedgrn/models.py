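"""Right-hand sides of every dynamical model in the package.

All RHS functions accept state arrays whose *last* axis indexes the model
variables, and broadcast over any leading axes, so the same code serves
single states, batched Newton iterations and vectorised ensembles.

Variable conventions:

* toggle and Z-U module: state = (z, u)
* X-Y module: state = (x, y)
* three-gene systems: state = (x, y, z)

States are assumed non-negative; RHS evaluation itself never clamps
(clamping is the stochastic integrator's job).
"""

from __future__ import annotations

import numpy as np

from .params import (
    NO_SWITCH,
    QuadModelParams,
    SwitchSchedule,
    ToggleParams,
    TwoNodeParams,
)

__all__ = [
    "toggle_rhs",
    "twonode_rhs",
    "k_star",
    "gata_switch_rhs",
    "tristable_rhs",
    "quad_rhs",
]


def _split(state, dim: int):
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != dim:
        raise ValueError(f"expected state with last axis of size {dim}, got shape {state.shape}")
    return state, tuple(state[..., i] for i in range(dim))


def toggle_rhs(state, params: ToggleParams) -> np.ndarray:
    """Symmetric Hill-repression toggle switch: two mutually repressing genes."""
    state, (z, u) = _split(state, 2)
    dz = params.basal + params.strength / (1.0 + u**params.hill) - z
    du = params.basal + params.strength / (1.0 + z**params.hill) - u
    return np.stack([dz, du], axis=-1)


def _sa_production(v, other, gain, self_sat, cross, basal=0.0):
    """Shea-Ackers production: (basal + gain*v) / ((1 + self_sat*v)(1 + cross*other))."""
    return (basal + gain * v) / ((1.0 + self_sat * v) * (1.0 + cross * other))


def twonode_rhs(state, params: TwoNodeParams) -> np.ndarray:
    """Double-negative feedback loop with positive autoregulation (two nodes).

    ``d/dt v1 = gain1*v1/((1+self_sat1*v1)(1+cross1*v2)) - deg1*v1`` and
    symmetrically for ``v2``.  The origin is always an equilibrium because
    every term is proportional to its own variable.
    """
    state, (v1, v2) = _split(state, 2)
    p1, p2 = params.first, params.second
    d1 = _sa_production(v1, v2, p1.gain, p1.self_sat, p1.cross) - p1.deg * v1
    d2 = _sa_production(v2, v1, p2.gain, p2.self_sat, p2.cross) - p2.deg * v2
    return np.stack([d1, d2], axis=-1)


def k_star(t, sched: SwitchSchedule):
    """Time-windowed displacement rate: ``k0_star`` on the closed window, else 0.

    Accepts scalar or array ``t``; boundary times belong to the window.
    """
    t = np.asarray(t, dtype=float)
    inside = (t >= sched.t1) & (t <= sched.t2)
    out = np.where(inside, sched.k0_star, 0.0)
    return out if out.ndim else float(out)


def gata_switch_rhs(state, params: TwoNodeParams, sched: SwitchSchedule, t) -> np.ndarray:
    """Two-node module with time-windowed displacement of the first gene.

    During the window the first gene loses mass at rate ``k*(t)`` and the
    second gene gains it at rate ``psi * k*(t)`` (transfer ratio ``psi``).
    With ``k0_star = 0`` this is exactly :func:`twonode_rhs`.
    """
    state, (z, u) = _split(state, 2)
    ks = k_star(t, sched)
    base = twonode_rhs(state, params)
    dz = base[..., 0] - ks * z
    du = base[..., 1] + sched.psi * ks * z
    return np.stack([dz, du], axis=-1)


def tristable_rhs(state, xy: TwoNodeParams, zu: TwoNodeParams) -> np.ndarray:
    """Three-gene system obtained by embedding an X-Y loop into a Z-U loop.

    The auxiliary u is replaced by x + y in the z-equation, and the x/y
    production terms inherit the repression of u by z (factor
    ``1/(1 + d2*z)`` with ``d2 = zu.second.cross``).
    """
    state, (x, y, z) = _split(state, 3)
    px, py = xy.first, xy.second
    pz = zu.first
    d2 = zu.second.cross
    rep_z = 1.0 + d2 * z
    dx = _sa_production(x, y, px.gain, px.self_sat, px.cross) / rep_z - px.deg * x
    dy = _sa_production(y, x, py.gain, py.self_sat, py.cross) / rep_z - py.deg * y
    dz = _sa_production(z, x + y, pz.gain, pz.self_sat, pz.cross) - pz.deg * z
    return np.stack([dx, dy, dz], axis=-1)


def quad_rhs(
    state,
    params: QuadModelParams,
    sched: SwitchSchedule = NO_SWITCH,
    t: float = 0.0,
) -> np.ndarray:
    """Modified three-gene model with basal production, weak z-to-x activation
    and the time-windowed displacement mechanism.

    With all basal constants, ``d_star`` and ``k0_star`` equal to zero this
    reduces exactly to :func:`tristable_rhs`.
    """
    state, (x, y, z) = _split(state, 3)
    px, py = params.xy.first, params.xy.second
    pz = params.zu.first
    d2 = params.zu.second.cross
    ks = k_star(t, sched)

    dx = (
        _sa_production(x, y, px.gain, px.self_sat, px.cross, basal=params.basal_x)
        * (1.0 + params.d_star * z)
        / (1.0 + d2 * z)
        - px.deg * x
        + sched.psi * ks * z
    )
    dy = (
        _sa_production(y, x, py.gain, py.self_sat, py.cross, basal=params.basal_y)
        / (1.0 + d2 * z)
        - py.deg * y
    )
    dz = (
        _sa_production(z, x + y, pz.gain, pz.self_sat, pz.cross, basal=params.basal_z)
        - pz.deg * z
        - ks * z
    )
    return np.stack([dx, dy, dz], axis=-1)
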