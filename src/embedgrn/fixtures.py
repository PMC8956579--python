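"""Packaged parameter fixtures and the fixture-file generator.

The bistable-case draws below were located by ``screen_bistability(10000,
seed=0)`` (first draw of each case; the perturbation demo draw is the 91st
case-1 draw, chosen because its perturbations reach case 2 at every default
strength).  The quad-stable set was found by a constrained random search over
uniform [0, 10] coefficients gated by the closed-form tristability conditions,
followed by a stochastic-balance refinement; it is shipped frozen because the
discovery search is far too expensive to re-run at import time.  All fixtures
re-verify their advertised properties in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import save_config
from .equilibria import STABLE, find_equilibria
from .inference import TimeSeriesData, synth_target
from .models import quad_rhs
from .params import (
    NoiseParams,
    QuadModelParams,
    SwitchSchedule,
    ToggleParams,
    TwoNodeParams,
)
from .stochastic import LabeledState, label_stable_states

__all__ = [
    "toggle_fixture",
    "bistable_case_fixture",
    "perturbation_demo_fixture",
    "quad_fixture",
    "default_schedule",
    "default_noise",
    "quad_stable_states",
    "synthetic_timeseries",
    "make_fixtures",
]


def toggle_fixture() -> ToggleParams:
    """The classic toggle-switch parameter set (basal 0.2, strength 4, hill 3)."""
    return ToggleParams(basal=0.2, strength=4.0, hill=3.0)


_CASE_DRAWS = {
    "case1": [
        7.192197728267403, 0.15991729523571974, 7.579510023564281, 5.1275872326207805,
        9.291042207970062, 0.6608249672407474, 8.413172796123833, 0.666900087671014,
    ],
    "case2": [
        9.598777393312224, 7.810431906790911, 4.644877010839129, 0.35645917294904184,
        8.320684093515908, 0.42103528225860054, 0.17213505068317092, 5.401886112032219,
    ],
    "case3": [
        6.1121896088065055, 0.7105877467879063, 1.5004937214105474, 3.381227085094418,
        9.749670230735731, 6.205857230780438, 2.7423488410833405, 1.9668344506732072,
    ],
}

_PERTURBATION_DEMO_DRAW = [
    6.234657186510095, 5.665998439148195, 8.892460695402885, 2.637417644552272,
    5.6089115348200105, 2.00060145400486, 1.9952704921082698, 4.165530027186433,
]


def bistable_case_fixture(case: str) -> TwoNodeParams:
    """A screened uniform draw exhibiting the requested bistability case."""
    try:
        return TwoNodeParams.from_array(np.array(_CASE_DRAWS[case]))
    except KeyError:
        raise ValueError(f"unknown case: {case!r}; expected one of {sorted(_CASE_DRAWS)}")


def perturbation_demo_fixture() -> TwoNodeParams:
    """A case-1 draw whose perturbations demonstrably reach case 2."""
    return TwoNodeParams.from_array(np.array(_PERTURBATION_DEMO_DRAW))


# Quad-stable coefficient set (see module docstring); canonical 8-vectors for
# the two sub-systems plus basal constants and the weak z-to-x activation.
_QUAD_XY = [
    3.12561224, 0.60064188, 2.82485867, 1.55859572,
    5.21791221, 0.11880538, 7.95611776, 4.81069663,
]
_QUAD_ZU = [
    8.35035487, 1.58209432, 10.72600687, 2.07715784,
    1.44572775, 7.06023015, 8.33563554, 6.5529745,
]
_QUAD_BASAL = [0.10612856, 2.14567592, 0.15078073]
_QUAD_DSTAR = 0.03491633


def quad_fixture() -> QuadModelParams:
    """The packaged quad-stable parameter set (four stable states, three saddles)."""
    return QuadModelParams(
        basal_x=_QUAD_BASAL[0],
        basal_y=_QUAD_BASAL[1],
        basal_z=_QUAD_BASAL[2],
        d_star=_QUAD_DSTAR,
        xy=TwoNodeParams.from_array(np.array(_QUAD_XY)),
        zu=TwoNodeParams.from_array(np.array(_QUAD_ZU)),
    )


def default_schedule(k0_star: float = 0.52, psi: float = 0.0005) -> SwitchSchedule:
    """Displacement schedule with the reference window [500, 3500]."""
    return SwitchSchedule(k0_star=k0_star, t1=500.0, t2=3500.0, psi=psi)


def default_noise() -> NoiseParams:
    """Reference noise strengths (0.04, 0.08, 0.08)."""
    return NoiseParams(omega1=0.04, omega2=0.08, omega3=0.08)


def quad_stable_states(
    params: QuadModelParams | None = None, high_ratio: float = 10.0
) -> list[LabeledState]:
    """Locate and label the stable states of a quad parameter set at runtime."""
    params = params or quad_fixture()
    hi = 2.0 * max(
        params.xy.first.gain / params.xy.first.deg,
        params.xy.second.gain / params.xy.second.deg,
        params.zu.first.gain / params.zu.first.deg,
        1.0,
    )
    eqs = find_equilibria(lambda s: quad_rhs(s, params), [[0.0, hi]] * 3, n_random=120, seed=1)
    stable = [e.state for e in eqs if e.classification == STABLE]
    return label_stable_states(stable, high_ratio=high_ratio)


def synthetic_timeseries(
    seed: int = 0,
    m: int = 10,
    noise_sd: float = 0.1,
    t_max: float = 6.0,
) -> TimeSeriesData:
    """Synthetic two-gene time course from the case-2 fixture (ABC demo data)."""
    timepoints = np.linspace(0.5, t_max, m)
    return synth_target(
        bistable_case_fixture("case2"), timepoints, noise_sd, seed=seed, init=(0.5, 0.5)
    )


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write every packaged fixture to ``outdir`` and return a manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    save_config(outdir / "toggle.yaml", toggle=toggle_fixture())
    for case in ("case1", "case2", "case3"):
        save_config(outdir / f"bistable_{case}.yaml", xy=bistable_case_fixture(case))
    save_config(outdir / "perturbation_demo.yaml", xy=perturbation_demo_fixture())
    save_config(
        outdir / "quad.yaml",
        quad=quad_fixture(),
        schedule=default_schedule(),
        noise=default_noise(),
    )
    ts = synthetic_timeseries(seed=seed)
    ts.to_csv(outdir / "timeseries.csv")

    manifest = {
        "seed": seed,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
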