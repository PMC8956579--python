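"""Typed parameter sets for the regulatory-network models.

Every model in the package is parameterised by one of the frozen dataclasses
below.  Validation happens at construction time so that downstream numerical
code can assume well-formed inputs.

Symbol correspondence
---------------------
The two double-negative-feedback sub-systems use different symbol families in
the literature.  :class:`TwoNodeParams` stores them under neutral names; the
table below documents the correspondence.

===========  ==============  ==============
field        Z-U sub-system  X-Y sub-system
===========  ==============  ==============
first node
  gain       a1              alpha1
  self_sat   b1              beta1
  cross      b2              beta2
  deg        k1              k3
second node
  gain       c1              gamma1
  self_sat   d1              sigma1
  cross      d2              sigma2
  deg        k2              k4
===========  ==============  ==============

``cross`` of a node is the coefficient with which the *other* node represses
this node's production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ToggleParams",
    "NodeParams",
    "TwoNodeParams",
    "SwitchSchedule",
    "NoiseParams",
    "QuadModelParams",
    "NO_SWITCH",
    "TWONODE_PARAM_NAMES",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class ToggleParams:
    """Symmetric two-gene toggle switch with Hill-type cross repression.

    ``d/dt z = basal + strength / (1 + u**hill) - z`` and symmetrically for
    ``u``.  Degradation rate is fixed at 1 (time is measured in units of the
    protein lifetime).
    """

    basal: float = 0.2
    strength: float = 4.0
    hill: float = 3.0

    def __post_init__(self) -> None:
        _require(self.basal > 0, "basal production must be > 0")
        _require(self.strength > 0, "repressible production strength must be > 0")
        _require(self.hill > 0 and math.isfinite(self.hill), "hill exponent must be finite and > 0")


@dataclass(frozen=True)
class NodeParams:
    """One node of a double-negative feedback loop with positive autoregulation.

    Production follows the Shea-Ackers form
    ``gain * v / ((1 + self_sat * v) * (1 + cross * other))`` with first-order
    degradation ``deg * v``.
    """

    gain: float
    self_sat: float
    cross: float
    deg: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")
        _require(self.deg > 0, "degradation rate must be > 0")


@dataclass(frozen=True)
class TwoNodeParams:
    """Parameter set of a two-node double-negative feedback sub-system.

    See the module docstring for the symbol correspondence between the
    neutral field names and the Z-U / X-Y symbol families.
    """

    first: NodeParams
    second: NodeParams

    @classmethod
    def from_values(
        cls,
        gain1: float,
        self_sat1: float,
        cross1: float,
        deg1: float,
        gain2: float,
        self_sat2: float,
        cross2: float,
        deg2: float,
    ) -> "TwoNodeParams":
        return cls(
            NodeParams(gain1, self_sat1, cross1, deg1),
            NodeParams(gain2, self_sat2, cross2, deg2),
        )

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 8-vector (first node then second node)."""
        a, b = self.first, self.second
        return np.array(
            [a.gain, a.self_sat, a.cross, a.deg, b.gain, b.self_sat, b.cross, b.deg],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values) -> "TwoNodeParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValueError(f"expected 8 parameter values, got shape {values.shape}")
        return cls.from_values(*values)


#: Canonical ordering of the flattened two-node parameter vector.
TWONODE_PARAM_NAMES = (
    "gain1",
    "self_sat1",
    "cross1",
    "deg1",
    "gain2",
    "self_sat2",
    "cross2",
    "deg2",
)


@dataclass(frozen=True)
class SwitchSchedule:
    """Time-windowed displacement rate with transfer efficiency.

    The displacement rate is ``k0_star`` for ``t`` in the closed interval
    ``[t1, t2]`` and zero otherwise; ``psi`` controls how much of the
    displaced flux is transferred to the receiving gene.
    """

    k0_star: float
    t1: float
    t2: float
    psi: float

    def __post_init__(self) -> None:
        _require(self.k0_star >= 0, "k0_star must be >= 0")
        _require(self.psi >= 0, "psi must be >= 0")
        _require(math.isfinite(self.t1) and math.isfinite(self.t2), "window bounds must be finite")
        _require(self.t1 <= self.t2, "window start must not exceed window end")


#: Schedule with the displacement mechanism switched off entirely.
NO_SWITCH = SwitchSchedule(k0_star=0.0, t1=0.0, t2=0.0, psi=0.0)


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative noise strengths on the three degradation/switching fluxes."""

    omega1: float
    omega2: float
    omega3: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")


@dataclass(frozen=True)
class QuadModelParams:
    """Three-gene model with basal production and a weak positive cross-regulation.

    Extends the embedded three-node system with basal production constants
    (``basal_x``, ``basal_y``, ``basal_z``) and a weak activation of gene x by
    gene z with coefficient ``d_star``.  The remaining coefficients are taken
    from the two sub-system parameter sets: ``xy`` provides the x- and
    y-equations, ``zu.first`` the z-equation, and ``zu.second.cross`` the
    strength with which z represses x and y production.
    """

    basal_x: float
    basal_y: float
    basal_z: float
    d_star: float
    xy: TwoNodeParams
    zu: TwoNodeParams

    def __post_init__(self) -> None:
        for name in ("basal_x", "basal_y", "basal_z", "d_star"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
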