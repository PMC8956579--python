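"""Structured config-file (YAML) serialisation of parameter sets.

The on-disk format is flat key->number maps, one section per sub-system plus
``schedule`` and ``noise`` sections:

.. code-block:: yaml

    toggle:   {basal: 0.2, strength: 4.0, hill: 3.0}
    xy:       {gain1: ..., self_sat1: ..., cross1: ..., deg1: ...,
               gain2: ..., self_sat2: ..., cross2: ..., deg2: ...}
    zu:       {gain1: ..., ...}
    quad:     {basal_x: ..., basal_y: ..., basal_z: ..., d_star: ...}
    schedule: {k0_star: ..., t1: ..., t2: ..., psi: ...}
    noise:    {omega1: ..., omega2: ..., omega3: ...}

Only the sections a run needs have to be present.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .params import (
    NoiseParams,
    QuadModelParams,
    SwitchSchedule,
    ToggleParams,
    TwoNodeParams,
)

__all__ = ["load_config", "save_config", "quad_from_sections", "sections_from_quad"]

_TWONODE_KEYS = (
    "gain1", "self_sat1", "cross1", "deg1", "gain2", "self_sat2", "cross2", "deg2",
)


def _twonode_to_dict(p: TwoNodeParams) -> dict:
    return dict(zip(_TWONODE_KEYS, (float(v) for v in p.to_array())))


def _twonode_from_dict(d: dict) -> TwoNodeParams:
    return TwoNodeParams.from_values(*(float(d[k]) for k in _TWONODE_KEYS))


def save_config(path, **sections) -> None:
    """Write named parameter objects to a YAML config file.

    Recognised keyword names: ``toggle``, ``xy``, ``zu``, ``quad``,
    ``schedule``, ``noise``.  ``quad`` expects a :class:`QuadModelParams` and
    is stored as its basal section plus ``xy``/``zu`` sections.
    """
    doc: dict = {}
    for name, obj in sections.items():
        if obj is None:
            continue
        if name == "toggle":
            doc["toggle"] = {k: float(v) for k, v in asdict(obj).items()}
        elif name in ("xy", "zu"):
            doc[name] = _twonode_to_dict(obj)
        elif name == "schedule":
            doc["schedule"] = {k: float(v) for k, v in asdict(obj).items()}
        elif name == "noise":
            doc["noise"] = {k: float(v) for k, v in asdict(obj).items()}
        elif name == "quad":
            doc.update(sections_from_quad(obj))
        else:
            raise ValueError(f"unknown config section: {name!r}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def sections_from_quad(quad: QuadModelParams) -> dict:
    return {
        "quad": {
            "basal_x": float(quad.basal_x),
            "basal_y": float(quad.basal_y),
            "basal_z": float(quad.basal_z),
            "d_star": float(quad.d_star),
        },
        "xy": _twonode_to_dict(quad.xy),
        "zu": _twonode_to_dict(quad.zu),
    }


def quad_from_sections(doc: dict) -> QuadModelParams:
    q = doc["quad"]
    return QuadModelParams(
        basal_x=float(q["basal_x"]),
        basal_y=float(q["basal_y"]),
        basal_z=float(q["basal_z"]),
        d_star=float(q["d_star"]),
        xy=_twonode_from_dict(doc["xy"]),
        zu=_twonode_from_dict(doc["zu"]),
    )


def load_config(path) -> dict:
    """Read a config file back into typed parameter objects.

    Returns a dict with whichever of the keys ``toggle``, ``xy``, ``zu``,
    ``quad``, ``schedule``, ``noise`` the file defines.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    if "toggle" in doc:
        out["toggle"] = ToggleParams(**{k: float(v) for k, v in doc["toggle"].items()})
    if "xy" in doc:
        out["xy"] = _twonode_from_dict(doc["xy"])
    if "zu" in doc:
        out["zu"] = _twonode_from_dict(doc["zu"])
    if "schedule" in doc:
        out["schedule"] = SwitchSchedule(**{k: float(v) for k, v in doc["schedule"].items()})
    if "noise" in doc:
        out["noise"] = NoiseParams(**{k: float(v) for k, v in doc["noise"].items()})
    if "quad" in doc:
        out["quad"] = quad_from_sections(doc)
    return out
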