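"""Structural embedding of a bistable sub-system into another.

A sub-system is described by *term descriptors* (production factors, basal
constants, linear losses) rather than symbolic algebra, so the embedded
system is exactly evaluatable and testable.  The embedding replaces each
auxiliary variable of the primary sub-system by a non-negative linear
combination of the secondary sub-system's variables, and propagates the
regulation that the primary exerted on the auxiliary onto every production
term of the secondary.

Two production families are supported: Hill-type repressible production
(``scale / prod(1 + coef * v**hill)``) and Shea-Ackers production
(``(basal + gain*v) / (1 + self_sat*v) * prod 1/(1 + coef*v)``).  These are
the only shapes for which the induced-regulation rewrite is defined here;
anything else raises :class:`UnsupportedTermError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .params import ToggleParams, TwoNodeParams

__all__ = [
    "Repressor",
    "HillProduction",
    "SAProduction",
    "Constant",
    "LinearLoss",
    "StructuredSystem",
    "SubsystemSpec",
    "EmbeddingMap",
    "EmbeddedSystem",
    "embed",
    "induced_regulation_factor",
    "toggle_subsystem",
    "twonode_subsystem",
    "UnsupportedTermError",
    "EmbeddingConfigError",
]


class UnsupportedTermError(TypeError):
    """Raised when an induced-regulation rewrite meets a term shape it cannot handle."""


class EmbeddingConfigError(ValueError):
    """Raised for inconsistent sub-system / map configurations."""


@dataclass(frozen=True)
class Repressor:
    """A multiplicative factor ``1 / (1 + coef * v**hill)``.

    ``weights`` defines the argument ``v`` as a non-negative linear
    combination of named variables, which lets substituted auxiliaries
    (e.g. ``u -> x + y``) stay exactly evaluatable.
    """

    weights: tuple[tuple[str, float], ...]
    coef: float
    hill: float = 1.0

    @classmethod
    def of(cls, var: str, coef: float, hill: float = 1.0) -> "Repressor":
        return cls(weights=((var, 1.0),), coef=coef, hill=hill)

    def argument(self, values: Mapping[str, np.ndarray]):
        return sum(w * values[name] for name, w in self.weights)

    def factor(self, values: Mapping[str, np.ndarray]):
        return 1.0 / (1.0 + self.coef * self.argument(values) ** self.hill)

    def variables(self) -> set[str]:
        return {name for name, _ in self.weights}


@dataclass(frozen=True)
class HillProduction:
    """``scale`` damped by any number of Hill repression factors."""

    scale: float
    repressors: tuple[Repressor, ...] = ()

    def __call__(self, values):
        out = self.scale
        for r in self.repressors:
            out = out * r.factor(values)
        return out


@dataclass(frozen=True)
class SAProduction:
    """Shea-Ackers production with self-saturation and repression factors."""

    var: str
    gain: float
    self_sat: float
    basal: float = 0.0
    repressors: tuple[Repressor, ...] = ()

    def __call__(self, values):
        v = values[self.var]
        out = (self.basal + self.gain * v) / (1.0 + self.self_sat * v)
        for r in self.repressors:
            out = out * r.factor(values)
        return out


@dataclass(frozen=True)
class Constant:
    """A constant (basal) production term."""

    value: float

    def __call__(self, values):
        return self.value


@dataclass(frozen=True)
class LinearLoss:
    """First-order degradation ``-rate * var``."""

    var: str
    rate: float

    def __call__(self, values):
        return -self.rate * values[self.var]


Term = HillProduction | SAProduction | Constant | LinearLoss


@dataclass(frozen=True)
class StructuredSystem:
    """A vector field given as per-variable sums of term descriptors."""

    variables: tuple[str, ...]
    equations: Mapping[str, tuple[Term, ...]]

    def __post_init__(self):
        missing = set(self.variables) - set(self.equations)
        if missing:
            raise EmbeddingConfigError(f"no equation for variables: {sorted(missing)}")

    def rhs(self, state) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape[-1] != len(self.variables):
            raise ValueError(
                f"state dimension {state.shape[-1]} != system dimension {len(self.variables)}"
            )
        values = {name: state[..., i] for i, name in enumerate(self.variables)}
        parts = []
        for name in self.variables:
            total = sum(term(values) for term in self.equations[name])
            parts.append(np.broadcast_to(total, state[..., 0].shape))
        return np.stack(parts, axis=-1)

    __call__ = rhs


@dataclass(frozen=True)
class SubsystemSpec:
    """A structured sub-system plus the names of its auxiliary variables."""

    system: StructuredSystem
    auxiliaries: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.auxiliaries) - set(self.system.variables)
        if unknown:
            raise EmbeddingConfigError(f"auxiliaries not in variable list: {sorted(unknown)}")


@dataclass(frozen=True)
class EmbeddingMap:
    """Per-auxiliary non-negative linear substitution rules.

    ``rules[aux]`` maps secondary variable names to coefficients; the default
    use is the plain sum (all coefficients 1).
    """

    rules: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        for aux, rule in self.rules.items():
            for var, coef in rule.items():
                if coef < 0:
                    raise EmbeddingConfigError(
                        f"negative coefficient {coef} for {var} in rule for {aux}"
                    )

    @classmethod
    def sum_of(cls, aux: str, variables: Sequence[str]) -> "EmbeddingMap":
        return cls({aux: {v: 1.0 for v in variables}})


@dataclass(frozen=True)
class EmbeddedSystem:
    """Result of embedding: a combined structured system over all retained variables."""

    system: StructuredSystem
    primary_variables: tuple[str, ...]
    secondary_variables: tuple[str, ...]

    @property
    def variables(self) -> tuple[str, ...]:
        return self.system.variables

    def rhs(self, state) -> np.ndarray:
        return self.system.rhs(state)

    __call__ = rhs


def induced_regulation_factor(term: Term, repressor: Repressor) -> Term:
    """Attach a repression factor to a production term.

    Production terms gain the extra multiplicative factor; a zero-coefficient
    repressor leaves the term unchanged.  Constants and losses are not
    production terms and raise :class:`UnsupportedTermError`.
    """
    if repressor.coef == 0.0:
        return term
    if isinstance(term, (HillProduction, SAProduction)):
        return replace(term, repressors=term.repressors + (repressor,))
    raise UnsupportedTermError(
        f"cannot apply an induced regulation factor to a {type(term).__name__} term"
    )


def _substitute(repressor: Repressor, rules: Mapping[str, Mapping[str, float]]) -> Repressor:
    """Expand auxiliary names inside a repressor argument via the linear rules."""
    new_weights: dict[str, float] = {}
    for name, w in repressor.weights:
        if name in rules:
            for var, coef in rules[name].items():
                new_weights[var] = new_weights.get(var, 0.0) + w * coef
        else:
            new_weights[name] = new_weights.get(name, 0.0) + w
    return replace(repressor, weights=tuple(sorted(new_weights.items())))


def embed(primary: SubsystemSpec, secondary: SubsystemSpec, emap: EmbeddingMap) -> EmbeddedSystem:
    """Couple two sub-systems by substituting the primary's auxiliaries.

    Each auxiliary of the primary is replaced, wherever it appears in the
    retained primary equations, by its linear combination of secondary
    variables.  In exchange, every production term of the secondary inherits
    the repression factors that acted on the auxiliary's own production in
    the primary (restricted to factors that reference retained primary
    variables).  The auxiliary equations are dropped.  Variable order of the
    result is secondary variables first, then retained primary variables.
    """
    aux = set(primary.auxiliaries)
    if set(emap.rules) != aux:
        raise EmbeddingConfigError(
            f"map rules {sorted(emap.rules)} do not match auxiliaries {sorted(aux)}"
        )
    sec_vars = set(secondary.system.variables)
    for a, rule in emap.rules.items():
        unknown = set(rule) - sec_vars
        if unknown:
            raise EmbeddingConfigError(
                f"rule for {a} references unknown secondary variables: {sorted(unknown)}"
            )
    overlap = set(primary.system.variables) & sec_vars
    if overlap:
        raise EmbeddingConfigError(f"variable name collision between sub-systems: {sorted(overlap)}")

    kept_primary = tuple(v for v in primary.system.variables if v not in aux)

    # repression factors the primary imposed on each auxiliary's production,
    # restricted to retained primary variables: these are induced onto the
    # secondary's production terms
    induced: list[Repressor] = []
    for a in primary.auxiliaries:
        for term in primary.system.equations[a]:
            if isinstance(term, (HillProduction, SAProduction)):
                for r in term.repressors:
                    if r.variables() <= set(kept_primary):
                        induced.append(r)

    equations: dict[str, tuple[Term, ...]] = {}
    for v in secondary.system.variables:
        new_terms = []
        for term in secondary.system.equations[v]:
            if isinstance(term, (HillProduction, SAProduction)):
                for r in induced:
                    term = induced_regulation_factor(term, r)
            new_terms.append(term)
        equations[v] = tuple(new_terms)

    for v in kept_primary:
        new_terms = []
        for term in primary.system.equations[v]:
            if isinstance(term, (HillProduction, SAProduction)):
                term = replace(
                    term,
                    repressors=tuple(_substitute(r, emap.rules) for r in term.repressors),
                )
            elif isinstance(term, LinearLoss) and term.var in aux:
                raise UnsupportedTermError(
                    f"linear loss of auxiliary {term.var} in a retained equation"
                )
            new_terms.append(term)
        equations[v] = tuple(new_terms)

    variables = secondary.system.variables + kept_primary
    system = StructuredSystem(variables=variables, equations=equations)
    return EmbeddedSystem(
        system=system,
        primary_variables=kept_primary,
        secondary_variables=secondary.system.variables,
    )


# ---------------------------------------------------------------------------
# Builders for the two model families
# ---------------------------------------------------------------------------

def toggle_subsystem(
    params: ToggleParams,
    variables: tuple[str, str] = ("z", "u"),
    auxiliaries: tuple[str, ...] = (),
) -> SubsystemSpec:
    """Structured form of the symmetric Hill toggle switch."""
    v1, v2 = variables
    equations = {
        v1: (
            Constant(params.basal),
            HillProduction(params.strength, (Repressor.of(v2, 1.0, params.hill),)),
            LinearLoss(v1, 1.0),
        ),
        v2: (
            Constant(params.basal),
            HillProduction(params.strength, (Repressor.of(v1, 1.0, params.hill),)),
            LinearLoss(v2, 1.0),
        ),
    }
    return SubsystemSpec(StructuredSystem(variables, equations), auxiliaries)


def twonode_subsystem(
    params: TwoNodeParams,
    variables: tuple[str, str] = ("z", "u"),
    auxiliaries: tuple[str, ...] = (),
) -> SubsystemSpec:
    """Structured form of the Shea-Ackers double-negative feedback loop."""
    v1, v2 = variables
    p1, p2 = params.first, params.second
    equations = {
        v1: (
            SAProduction(v1, p1.gain, p1.self_sat, repressors=(Repressor.of(v2, p1.cross),)),
            LinearLoss(v1, p1.deg),
        ),
        v2: (
            SAProduction(v2, p2.gain, p2.self_sat, repressors=(Repressor.of(v1, p2.cross),)),
            LinearLoss(v2, p2.deg),
        ),
    }
    return SubsystemSpec(StructuredSystem(variables, equations), auxiliaries)
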