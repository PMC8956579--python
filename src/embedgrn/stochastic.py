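"""Ito SDE simulation of the three-gene model and ensemble/sweep analyses.

The integrator is a semi-implicit Euler scheme: production and switching
source terms are evaluated explicitly at the current state, the linear loss
terms are treated implicitly (closed-form division per component), and the
diffusion terms multiply independent N(0, dt) Wiener increments.  Negative
excursions are clamped to zero; the drift can re-grow basal expression, so
zero acts as an absorbing-then-releasing boundary.

Everything is vectorised over replicates, and the sweep additionally folds
all grid cells into one batched integration with per-replicate schedule
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import quad_rhs
from .params import NoiseParams, QuadModelParams, SwitchSchedule

__all__ = [
    "SDEConfig",
    "EnsembleResult",
    "LabeledState",
    "STATE_LABELS",
    "sde_step",
    "simulate_sde",
    "solve_quad_ode",
    "label_stable_states",
    "classify_endpoint",
    "run_ensemble",
    "sweep",
    "expression_distributions",
]

#: Endpoint labels: one gene uniquely high (G1H: x, P1H: y, G2H: z), all low,
#: or not attributable to any reference state.
STATE_LABELS = ("G2H", "G1H", "P1H", "LE3G", "unclassified")

GENES = ("x", "y", "z")


@dataclass(frozen=True)
class SDEConfig:
    dt: float
    t_end: float
    init: np.ndarray
    sched: SwitchSchedule
    noise: NoiseParams
    seed: int = 0

    def __post_init__(self):
        init = np.asarray(self.init, dtype=float)
        object.__setattr__(self, "init", init)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if init.shape != (3,) or np.any(init < 0):
            raise ValueError("init must be a non-negative 3-vector")


@dataclass(frozen=True)
class LabeledState:
    """A reference stable state with its endpoint label."""

    label: str
    state: np.ndarray


@dataclass(frozen=True)
class EnsembleResult:
    """Endpoint states and labels of a batch of stochastic replicates."""

    finals: np.ndarray  # (n, 3)
    labels: tuple[str, ...]
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.finals.shape[0]

    @property
    def counts(self) -> dict[str, int]:
        return {lab: sum(1 for l in self.labels if l == lab) for lab in STATE_LABELS}

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n_replicates
        return {lab: c / n for lab, c in self.counts.items()}


def _production(x, y, z, params: QuadModelParams):
    px, py = params.xy.first, params.xy.second
    pz = params.zu.first
    d2 = params.zu.second.cross
    prod_x = (
        (params.basal_x + px.gain * x)
        / ((1.0 + px.self_sat * x) * (1.0 + px.cross * y))
        * (1.0 + params.d_star * z)
        / (1.0 + d2 * z)
    )
    prod_y = (params.basal_y + py.gain * y) / (
        (1.0 + py.self_sat * y) * (1.0 + py.cross * x) * (1.0 + d2 * z)
    )
    prod_z = (params.basal_z + pz.gain * z) / (
        (1.0 + pz.self_sat * z) * (1.0 + pz.cross * (x + y))
    )
    return prod_x, prod_y, prod_z


def _step_arrays(x, y, z, t, dt, params, noise, k0, t1, t2, psi, dW):
    """One semi-implicit Euler step on component arrays; returns clamped arrays.

    ``k0``/``psi`` may be scalars or per-replicate arrays (used by the sweep).
    """
    ks = np.where((t >= t1) & (t <= t2), k0, 0.0)
    px, py = params.xy.first, params.xy.second
    k1 = params.zu.first.deg
    prod_x, prod_y, prod_z = _production(x, y, z, params)

    src_x = prod_x + psi * ks * z
    num_x = x + dt * src_x + noise.omega1 * (px.deg * x + psi * ks * z) * dW[0]
    num_y = y + dt * prod_y + noise.omega2 * (py.deg * y) * dW[1]
    num_z = z + dt * prod_z + noise.omega3 * ((k1 + ks) * z) * dW[2]

    x_new = np.clip(num_x / (1.0 + px.deg * dt), 0.0, None)
    y_new = np.clip(num_y / (1.0 + py.deg * dt), 0.0, None)
    z_new = np.clip(num_z / (1.0 + (k1 + ks) * dt), 0.0, None)
    return x_new, y_new, z_new


def sde_step(
    state,
    t: float,
    dt: float,
    params: QuadModelParams,
    sched: SwitchSchedule,
    noise: NoiseParams,
    rng: np.random.Generator,
):
    """Advance one (possibly batched) state by a single semi-implicit Euler step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state = np.asarray(state, dtype=float)
    squeeze = state.ndim == 1
    S = np.atleast_2d(state)
    dW = rng.normal(0.0, np.sqrt(dt), size=(3,) + S[:, 0].shape)
    x, y, z = _step_arrays(
        S[:, 0], S[:, 1], S[:, 2], t, dt, params, noise,
        sched.k0_star, sched.t1, sched.t2, sched.psi, dW,
    )
    out = np.stack([x, y, z], axis=-1)
    return out[0] if squeeze else out


def _integrate(
    states: np.ndarray,
    params: QuadModelParams,
    noise: NoiseParams,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    k0, t1, t2, psi,
    record_every: int = 0,
):
    """Batched integration loop; optionally records every ``record_every`` steps."""
    x, y, z = states[:, 0].copy(), states[:, 1].copy(), states[:, 2].copy()
    sqrt_dt = np.sqrt(dt)
    recorded = []
    times = []
    for i in range(n_steps):
        t = i * dt
        dW = rng.standard_normal((3,) + x.shape) * sqrt_dt
        x, y, z = _step_arrays(x, y, z, t, dt, params, noise, k0, t1, t2, psi, dW)
        if record_every and (i + 1) % record_every == 0:
            recorded.append(np.stack([x, y, z], axis=-1).copy())
            times.append((i + 1) * dt)
    final = np.stack([x, y, z], axis=-1)
    return final, (np.array(times), np.array(recorded) if recorded else None)


def simulate_sde(config: SDEConfig, params: QuadModelParams, record_every: int = 100):
    """One seeded trajectory; returns (times, states) sampled every ``record_every`` steps.

    The returned arrays include the initial state at t = 0.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.t_end / config.dt))
    states = config.init[None, :].copy()
    s = config.sched
    final, (times, rec) = _integrate(
        states, params, config.noise, config.dt, n_steps, rng,
        s.k0_star, s.t1, s.t2, s.psi, record_every=record_every,
    )
    if rec is None:
        times = np.array([0.0, n_steps * config.dt])
        traj = np.stack([config.init, final[0]])
    else:
        times = np.concatenate([[0.0], times])
        traj = np.concatenate([config.init[None, :], rec[:, 0, :]], axis=0)
    return times, traj


def solve_quad_ode(params: QuadModelParams, sched: SwitchSchedule, init, t_end, rtol=1e-9, atol=1e-11):
    """Reference deterministic solve; integrates piecewise across the window edges."""
    breaks = sorted({0.0, t_end} | {t for t in (sched.t1, sched.t2) if 0.0 < t < t_end})
    state = np.asarray(init, dtype=float)
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)  # k* is constant within a segment
        sol = solve_ivp(
            lambda t, s: quad_rhs(s, params, sched, mid),
            (a, b), state, rtol=rtol, atol=atol, method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"ODE solve failed on [{a}, {b}]: {sol.message}")
        state = sol.y[:, -1]
    return state


def label_stable_states(states: Sequence[np.ndarray], high_ratio: float = 10.0) -> list[LabeledState]:
    """Attach endpoint labels to reference stable states.

    A gene is *uniquely high* when its level exceeds ``high_ratio`` times each
    of the other two; otherwise the state is the all-low state.  Exactly one
    state per label is required.
    """
    out = []
    for s in states:
        s = np.asarray(s, dtype=float)
        labels_by_gene = ("G1H", "P1H", "G2H")  # x, y, z uniquely high
        label = "LE3G"
        for i in range(3):
            others = [s[j] for j in range(3) if j != i]
            if all(s[i] > high_ratio * o for o in others):
                label = labels_by_gene[i]
                break
        out.append(LabeledState(label, s))
    seen = [l.label for l in out]
    dupes = {l for l in seen if seen.count(l) > 1}
    if dupes:
        raise ValueError(f"multiple reference states share labels: {sorted(dupes)}")
    return out


def classify_endpoint(
    final_state,
    stable_states: Sequence[LabeledState],
    max_log_distance: float = 3.0,
    in_window: bool = False,
) -> str:
    """Label a final state by its nearest reference state on the ln(v+1) scale.

    Returns ``unclassified`` when the trajectory ended inside the switching
    window or when the nearest reference state is farther than
    ``max_log_distance`` in log coordinates.
    """
    if not stable_states:
        raise ValueError("need at least one reference stable state")
    if in_window:
        return "unclassified"
    f = np.log1p(np.asarray(final_state, dtype=float))
    best_label, best_d = None, np.inf
    for ref in stable_states:
        d = float(np.linalg.norm(f - np.log1p(ref.state)))
        # strict < keeps the first label in the supplied order on exact ties
        if d < best_d:
            best_label, best_d = ref.label, d
    return best_label if best_d <= max_log_distance else "unclassified"


def _classify_batch(finals, stable_states, max_log_distance, in_window):
    if in_window:
        return tuple("unclassified" for _ in range(finals.shape[0]))
    logf = np.log1p(finals)
    refs = np.stack([np.log1p(r.state) for r in stable_states])
    d = np.linalg.norm(logf[:, None, :] - refs[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)
    dmin = d[np.arange(len(idx)), idx]
    labels = [stable_states[i].label for i in idx]
    return tuple(
        lab if ok else "unclassified" for lab, ok in zip(labels, dmin <= max_log_distance)
    )


def run_ensemble(
    n_replicates: int,
    config: SDEConfig,
    params: QuadModelParams,
    stable_states: Sequence[LabeledState],
    max_log_distance: float = 3.0,
) -> EnsembleResult:
    """Independent seeded replicates with endpoint classification."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.t_end / config.dt))
    states = np.broadcast_to(config.init, (n_replicates, 3)).copy()
    s = config.sched
    finals, _ = _integrate(
        states, params, config.noise, config.dt, n_steps, rng,
        s.k0_star, s.t1, s.t2, s.psi,
    )
    in_window = s.k0_star > 0 and s.t1 <= config.t_end <= s.t2
    labels = _classify_batch(finals, list(stable_states), max_log_distance, in_window)
    return EnsembleResult(finals=finals, labels=labels, seed=config.seed)


def sweep(
    k0_values: Sequence[float],
    psi_values: Sequence[float],
    n_per_cell: int,
    params: QuadModelParams,
    base_config: SDEConfig,
    stable_states: Sequence[LabeledState],
    max_log_distance: float = 3.0,
) -> pd.DataFrame:
    """Ensemble summaries over a (k0_star, psi) grid.

    All cells are integrated in one batch with per-replicate schedule values.
    Per cell the table reports: the successful-switching fraction (endpoint
    label neither G2H nor unclassified), the ratio of P1H to G1H endpoints
    among switched replicates (NaN when undefined), a four-state-coexistence
    indicator, and the LE3G frequency.  Long format: one row per
    (k0_star, psi, metric).
    """
    k0_values = list(k0_values)
    psi_values = list(psi_values)
    cells = [(k0, psi) for k0 in k0_values for psi in psi_values]
    n_cells = len(cells)
    k0_rep = np.repeat([c[0] for c in cells], n_per_cell)
    psi_rep = np.repeat([c[1] for c in cells], n_per_cell)

    rng = np.random.default_rng(base_config.seed)
    n_steps = int(round(base_config.t_end / base_config.dt))
    states = np.broadcast_to(base_config.init, (n_cells * n_per_cell, 3)).copy()
    s = base_config.sched
    finals, _ = _integrate(
        states, params, base_config.noise, base_config.dt, n_steps, rng,
        k0_rep, s.t1, s.t2, psi_rep,
    )

    stable_states = list(stable_states)
    rows = []
    for ci, (k0, psi) in enumerate(cells):
        block = finals[ci * n_per_cell : (ci + 1) * n_per_cell]
        in_window = k0 > 0 and s.t1 <= base_config.t_end <= s.t2
        labels = _classify_batch(block, stable_states, max_log_distance, in_window)
        counts = {lab: labels.count(lab) for lab in STATE_LABELS}
        switched = counts["G1H"] + counts["P1H"] + counts["LE3G"]
        ratio = counts["P1H"] / counts["G1H"] if counts["G1H"] > 0 else np.nan
        metrics = {
            "switch_fraction": switched / n_per_cell,
            "gmp_mep_ratio": ratio if switched > 0 else np.nan,
            "four_states": float(all(counts[lab] > 0 for lab in ("G2H", "G1H", "P1H", "LE3G"))),
            "le3g_frequency": counts["LE3G"] / n_per_cell,
        }
        for metric, value in metrics.items():
            rows.append({"k0_star": k0, "psi": psi, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def expression_distributions(ensemble: EnsembleResult) -> pd.DataFrame:
    """Per-(state, gene) expression values on the ln(value + 1) scale.

    Long format suitable for violin rendering: columns label, gene, value.
    """
    rows = []
    log_vals = np.log1p(ensemble.finals)
    for i, lab in enumerate(ensemble.labels):
        for g, gene in enumerate(GENES):
            rows.append({"label": lab, "gene": gene, "value": log_vals[i, g]})
    return pd.DataFrame(rows)
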