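"""Equilibrium location and linear stability analysis.

Two complementary routes are provided for the two-node sub-system: closed-form
equilibria (axis states plus the interior states obtained from the nullcline
quadratic) and a generic multistart Newton solver that works for any RHS.
Their agreement is part of the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import twonode_rhs
from .params import TwoNodeParams

__all__ = [
    "Equilibrium",
    "classify",
    "jacobian",
    "axis_equilibria_2d",
    "interior_equilibria_2d",
    "find_equilibria",
    "default_box",
    "axis_stability_condition",
    "interior_stability_condition",
    "embedded_axis_stability_condition",
    "lifted_interior_stability_condition",
    "saddle_distances",
]

STABLE = "stable"
SADDLE = "saddle"
UNSTABLE = "unstable"
MARGINAL = "marginal"


@dataclass(frozen=True)
class Equilibrium:
    """A located steady state with its local stability information."""

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    classification: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        coords = ", ".join(f"{v:.6g}" for v in self.state)
        return f"Equilibrium(({coords}), {self.classification}, residual={self.residual:.2e})"


def classify(eigenvalues, tol: float = 1e-8) -> str:
    """Classify a spectrum by the signs of real parts at tolerance ``tol``.

    Any real part within ``tol`` of zero makes the point ``marginal``; the
    caller decides how to treat those, they are never silently coerced.
    """
    eigenvalues = np.atleast_1d(np.asarray(eigenvalues))
    if eigenvalues.size == 0:
        raise ValueError("cannot classify an empty spectrum")
    re = eigenvalues.real
    if np.any(np.abs(re) <= tol):
        return MARGINAL
    if np.all(re < 0):
        return STABLE
    if np.all(re > 0):
        return UNSTABLE
    return SADDLE


def jacobian(rhs: Callable[[np.ndarray], np.ndarray], point, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-coordinate relative step."""
    point = np.asarray(point, dtype=float)
    dim = point.shape[-1]
    J = np.empty((dim, dim))
    for j in range(dim):
        h = rel_step * max(1.0, abs(point[j]))
        ej = np.zeros(dim)
        ej[j] = h
        J[:, j] = (np.asarray(rhs(point + ej)) - np.asarray(rhs(point - ej))) / (2.0 * h)
    return J


def _make_equilibrium(rhs, state, eig_tol: float = 1e-8) -> Equilibrium:
    state = np.asarray(state, dtype=float)
    resid = float(np.max(np.abs(rhs(state))))
    eigs = np.linalg.eigvals(jacobian(rhs, state))
    return Equilibrium(state=state, residual=resid, eigenvalues=eigs, classification=classify(eigs, eig_tol))


# ---------------------------------------------------------------------------
# Closed-form equilibria of the two-node sub-system
# ---------------------------------------------------------------------------

def axis_equilibria_2d(params: TwoNodeParams, eig_tol: float = 1e-8) -> list[Equilibrium]:
    """Equilibria on the coordinate axes: the origin plus (v1e, 0) / (0, v2e).

    The on-axis coordinate is ``(gain - deg) / (deg * self_sat)``, present only
    when ``gain > deg`` (and ``self_sat > 0`` so the value is finite).
    """
    p1, p2 = params.first, params.second
    if p1.deg <= 0 or p2.deg <= 0:
        raise ValueError("degradation rates must be positive")
    rhs = lambda s: twonode_rhs(s, params)

    out = [_make_equilibrium(rhs, [0.0, 0.0], eig_tol)]
    if p1.gain > p1.deg and p1.self_sat > 0:
        xe = (p1.gain - p1.deg) / (p1.deg * p1.self_sat)
        out.append(_make_equilibrium(rhs, [xe, 0.0], eig_tol))
    if p2.gain > p2.deg and p2.self_sat > 0:
        ye = (p2.gain - p2.deg) / (p2.deg * p2.self_sat)
        out.append(_make_equilibrium(rhs, [0.0, ye], eig_tol))
    return out


def _interior_quadratic(params: TwoNodeParams) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of the nullcline-intersection quadratic in m = self_sat1 * x.

    Substitutions: A1 = cross1/self_sat2, A2 = gain1/deg1, B1 = cross2/self_sat1,
    B2 = gain2/deg2.
    """
    p1, p2 = params.first, params.second
    A1 = p1.cross / p2.self_sat
    A2 = p1.gain / p1.deg
    B1 = p2.cross / p1.self_sat
    B2 = p2.gain / p2.deg
    A = A1 * B1 - B1
    B = A1 - B1 - 1.0 + A1 * B1 - A1 * B2 + A2 * B1
    C = A1 + A2 - 1.0 - A1 * B2
    return A, B, C


def interior_equilibria_2d(
    params: TwoNodeParams,
    residual_tol: float = 1e-9,
    eig_tol: float = 1e-8,
) -> list[Equilibrium]:
    """Strictly positive equilibria of the two-node sub-system (at most two).

    Solves the quadratic in ``m = self_sat1 * x`` that the intersection of the
    two production nullclines satisfies, keeps the real roots with ``m > 0``,
    back-solves y from the first nullcline and retains points with ``y > 0``
    and a small residual.
    """
    p1, p2 = params.first, params.second
    if p1.self_sat <= 0 or p2.self_sat <= 0:
        # the quadratic substitutions are undefined; no autoregulation
        # saturation means no finite interior balance in this form
        return []
    rhs = lambda s: twonode_rhs(s, params)
    A, B, C = _interior_quadratic(params)

    if A == 0.0:
        roots = [-C / B] if B != 0.0 else []
    else:
        disc = B * B - 4.0 * A * C
        if disc < 0.0:
            return []
        sq = np.sqrt(disc)
        roots = [(-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)]

    out: list[Equilibrium] = []
    for m in roots:
        if not np.isfinite(m) or m <= 0.0:
            continue
        x = m / p1.self_sat
        # back-solve y from the x-nullcline; fall back to the y-nullcline
        if p1.cross > 0:
            y = (p1.gain / (p1.deg * (1.0 + m)) - 1.0) / p1.cross
        else:
            y = (p2.gain / (p2.deg * (1.0 + p2.cross * x)) - 1.0) / p2.self_sat
        if not np.isfinite(y) or y <= 0.0:
            continue
        state = np.array([x, y])
        if np.max(np.abs(rhs(state))) > residual_tol * max(1.0, x, y):
            continue
        out.append(_make_equilibrium(rhs, state, eig_tol))
    return out


# ---------------------------------------------------------------------------
# Generic multistart solver
# ---------------------------------------------------------------------------

def default_box(params: TwoNodeParams, extra: Sequence[float] = ()) -> np.ndarray:
    """Per-variable search box [0, 1.5 * max(gain/deg)], widened by ``extra`` hints."""
    p1, p2 = params.first, params.second
    hi = 1.5 * max(p1.gain / p1.deg, p2.gain / p2.deg, *extra, 1.0)
    return np.array([[0.0, hi], [0.0, hi]])


def _batched_jacobian(rhs, X, rel_step=1e-7):
    n, dim = X.shape
    J = np.empty((n, dim, dim))
    for j in range(dim):
        h = rel_step * np.maximum(1.0, np.abs(X[:, j]))
        E = np.zeros_like(X)
        E[:, j] = h
        J[:, :, j] = (rhs(X + E) - rhs(X - E)) / (2.0 * h)[:, None]
    return J


def find_equilibria(
    rhs: Callable[[np.ndarray], np.ndarray],
    box,
    n_random: int = 100,
    seed: int = 0,
    tol: float = 1e-10,
    dedup_radius: float = 1e-6,
    max_iter: int = 120,
    eig_tol: float = 1e-8,
    grid_per_dim: int = 5,
) -> list[Equilibrium]:
    """Multistart projected-Newton search for non-negative equilibria.

    Starts from a regular ``grid_per_dim**dim`` grid over ``box`` plus
    ``n_random`` seeded uniform draws; Newton iterates are projected onto the
    non-negative orthant.  Converged points (max-norm residual below ``tol``)
    are deduplicated within ``dedup_radius`` relative to the box extent.
    Deterministic for fixed (box, seed).  Returns an empty list when no start
    converges.
    """
    box = np.asarray(box, dtype=float)
    dim = box.shape[0]
    lo, hi = box[:, 0], box[:, 1]
    if not (np.all(np.isfinite(box)) and np.all(lo >= 0) and np.all(hi > lo)):
        raise ValueError("box bounds must be finite, non-negative and ordered")

    axes = [np.linspace(lo[d], hi[d], grid_per_dim) for d in range(dim)]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=-1)
    rng = np.random.default_rng(seed)
    rand = lo + (hi - lo) * rng.uniform(size=(n_random, dim))
    X = np.vstack([grid, rand])

    scale = float(np.max(hi - lo))
    for _ in range(max_iter):
        F = rhs(X)
        done = np.max(np.abs(F), axis=1) < 1e-14
        if np.all(done):
            break
        J = _batched_jacobian(rhs, X)
        # ridge-regularised solve; singular Jacobians get a tiny diagonal bump
        J = J + 1e-13 * np.eye(dim)
        try:
            step = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Ji, Fi, rcond=None)[0] for Ji, Fi in zip(J, F)])
        # cap the step to avoid wild excursions from near-singular points
        cap = 10.0 * scale
        norm = np.max(np.abs(step), axis=1, keepdims=True)
        step = np.where(norm > cap, step * cap / np.maximum(norm, 1e-300), step)
        X = np.clip(X - step, 0.0, None)
        X = np.where(np.isfinite(X), X, 0.0)

    F = rhs(X)
    ok = np.max(np.abs(F), axis=1) < tol
    X = X[ok]

    radius = dedup_radius * max(1.0, scale)
    reps: list[np.ndarray] = []
    for x in X:
        if not any(np.linalg.norm(x - r) <= radius for r in reps):
            reps.append(x)
    reps.sort(key=lambda r: tuple(np.round(r / max(radius, 1e-12))))
    return [_make_equilibrium(rhs, r, eig_tol) for r in reps]


# ---------------------------------------------------------------------------
# Closed-form stability conditions
# ---------------------------------------------------------------------------

def axis_stability_condition(params: TwoNodeParams, which: str) -> bool:
    """Closed-form stability/instability conditions for the axis equilibria.

    ``origin``: unstable when both gains exceed their degradation rates.
    ``x_axis`` / ``y_axis``: the on-axis state is stable when the opposing
    gene's effective growth rate at that point is below its degradation rate.
    """
    p1, p2 = params.first, params.second
    if which == "origin":
        return p1.gain > p1.deg and p2.gain > p2.deg
    if which == "x_axis":
        xe = (p1.gain - p1.deg) / (p1.deg * p1.self_sat)
        return p2.gain / (1.0 + p2.cross * xe) < p2.deg
    if which == "y_axis":
        ye = (p2.gain - p2.deg) / (p2.deg * p2.self_sat)
        return p1.gain / (1.0 + p1.cross * ye) < p1.deg
    raise ValueError(f"unknown equilibrium selector: {which!r}")


def interior_stability_condition(params: TwoNodeParams, point) -> bool:
    """Closed-form stability condition for a strictly positive equilibrium.

    Evaluates ``self_sat1*self_sat2*eta*xi - cross1*cross2*theta*rho > 0``
    with theta = 1 + self_sat1*x, eta = 1 + cross1*y, rho = 1 + self_sat2*y,
    xi = 1 + cross2*x, at the supplied point.
    """
    p1, p2 = params.first, params.second
    x, y = float(point[0]), float(point[1])
    theta = 1.0 + p1.self_sat * x
    eta = 1.0 + p1.cross * y
    rho = 1.0 + p2.self_sat * y
    xi = 1.0 + p2.cross * x
    return p1.self_sat * p2.self_sat * eta * xi - p1.cross * p2.cross * theta * rho > 0.0


def embedded_axis_stability_condition(xy: TwoNodeParams, zu: TwoNodeParams, which: str) -> bool:
    """Stability conditions for the axis equilibria of the embedded 3-D system.

    Assumes the corresponding 2-D stability (``axis_stability_condition``) already holds;
    the returned condition is the additional transverse requirement.
    """
    px, py = xy.first, xy.second
    pz = zu.first
    d2 = zu.second.cross
    if which == "x_axis":
        xe = (px.gain - px.deg) / (px.deg * px.self_sat)
        return pz.gain / (1.0 + pz.cross * xe) < pz.deg
    if which == "y_axis":
        ye = (py.gain - py.deg) / (py.deg * py.self_sat)
        return pz.gain / (1.0 + pz.cross * ye) < pz.deg
    if which == "z_axis":
        ze = (pz.gain - pz.deg) / (pz.deg * pz.self_sat)
        return (px.gain / (1.0 + d2 * ze) < px.deg) and (py.gain / (1.0 + d2 * ze) < py.deg)
    raise ValueError(f"unknown equilibrium selector: {which!r}")


def lifted_interior_stability_condition(xy: TwoNodeParams, zu: TwoNodeParams, point_xy) -> bool:
    """Transverse stability of a lifted interior state (x*, y*, 0).

    Given a stable interior state of the two-node sub-system, the lift is
    stable in 3-D when the third gene cannot grow against the combined
    repression: ``gain_z / (1 + cross_z * (x* + y*)) < deg_z``.
    """
    pz = zu.first
    s = float(point_xy[0]) + float(point_xy[1])
    return pz.gain / (1.0 + pz.cross * s) < pz.deg


def saddle_distances(equilibria: Sequence[Equilibrium]) -> pd.DataFrame:
    """Euclidean distances from each stable state to each saddle.

    Returns a table with one row per (stable, saddle) pair plus the minimum
    distance per stable state (a basin-size proxy).  Empty (with a warning)
    when there are no saddles.
    """
    stables = [e for e in equilibria if e.classification == STABLE]
    saddles = [e for e in equilibria if e.classification == SADDLE]
    if not saddles:
        warnings.warn("no saddle points among the supplied equilibria", stacklevel=2)
        return pd.DataFrame(columns=["stable", "saddle", "distance", "is_min"])
    rows = []
    for i, s in enumerate(stables):
        dists = [float(np.linalg.norm(s.state - c.state)) for c in saddles]
        dmin = min(dists)
        for j, d in enumerate(dists):
            rows.append({"stable": i, "saddle": j, "distance": d, "is_min": d == dmin})
    return pd.DataFrame(rows)
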