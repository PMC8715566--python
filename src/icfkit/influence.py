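"""Contextual factors and the Influence n-ary relation.

Contextual factors split into two disjoint kinds: environmental factors
(things that physically exist, carrying an e-code) and personal factors
(attributes of the person, not classified by the ICF and carrying no
code).  Their effect on functioning is reified as an ``Influence``
individual relating

* exactly one contextual factor (the ``factor`` relation),
* exactly one influenced target, via exactly one of the polarity
  relations ``facilitatedBy`` / ``hindrancedBy``,
* a level from the scale matching the polarity (``facilitationLevel``
  with Facilitation values XOR ``barrierLevel`` with Hindrance values),
* and optionally an ``influencingManner`` describing how the influence
  originates (the factor's presence, its absence, its accessibility, …).

The target's type realizes the ICF's three coding conventions for
environmental factors: an influence on a whole health state is
convention 1, on one component of a health state convention 2, and on a
single qualified activity convention 3.

``Facilitator`` and ``Barrier`` are defined classes over ``Influence``:
membership follows from the polarity relation alone, so classification
is total, deterministic and mutually exclusive.  ``InfluencingFactor``
is the defined class of contextual factors exerting at least one
influence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

from .codes import Component, ICFCode, parse_code
from .healthstate import HealthState, Model, ModelError, QualifiedActivity, slugify
from .qualifiers import FACILITATION, HINDRANCE, QualifierValue

__all__ = [
    "FactorKind",
    "Polarity",
    "InfluencingManner",
    "ContextualFactor",
    "InfluenceableComponent",
    "Influence",
    "InfluenceClass",
    "add_factor",
    "add_influence",
    "convention_of",
    "classify_influence",
    "influencing_factors",
]


class FactorKind(Enum):
    ENVIRONMENTAL = "environmental"
    PERSONAL = "personal"


class Polarity(Enum):
    FACILITATION = "facilitation"
    HINDRANCE = "hindrance"


class InfluencingManner(Enum):
    """How the factor's influence originates; a closed enumeration.

    A barrier may act through the factor's presence or its absence; a
    facilitator through the accessibility, dependability, variability
    or quality of the resource.  ``UNSPECIFIED`` covers assessments
    that record no origin.
    """

    PRESENCE = "presence"
    ABSENCE = "absence"
    ACCESSIBILITY = "accessibility"
    QUALITY = "quality"
    DEPENDABILITY = "dependability"
    VARIABILITY = "variability"
    UNSPECIFIED = "unspecified"


class InfluenceClass(Enum):
    """The two defined subclasses of Influence."""

    FACILITATOR = "Facilitator"
    BARRIER = "Barrier"


@dataclass(eq=False)
class ContextualFactor:
    """An environmental or personal factor.

    Environmental factors must carry a valid e-code; personal factors
    never carry one.
    """

    kind: FactorKind
    label: str
    short_name: str
    code: Optional[ICFCode] = None

    def __repr__(self) -> str:
        return f"ContextualFactor({self.short_name})"


@dataclass(eq=False)
class InfluenceableComponent:
    """Convention-2 target: one health-domain component of a health state."""

    health_state: HealthState
    component: Component
    short_name: str

    def __repr__(self) -> str:
        return f"InfluenceableComponent({self.short_name})"


InfluenceTarget = Union[HealthState, InfluenceableComponent, QualifiedActivity]


@dataclass(eq=False)
class Influence:
    """The reified influence relation (one factor, one target)."""

    factor: Optional[ContextualFactor]
    target: Optional[InfluenceTarget]
    short_name: str
    facilitation_level: Optional[QualifierValue] = None
    barrier_level: Optional[QualifierValue] = None
    manner: Optional[InfluencingManner] = None

    @property
    def polarity(self) -> Optional[Polarity]:
        if self.facilitation_level is not None and self.barrier_level is None:
            return Polarity.FACILITATION
        if self.barrier_level is not None and self.facilitation_level is None:
            return Polarity.HINDRANCE
        return None  # ill-formed: caught by validation

    @property
    def level(self) -> Optional[QualifierValue]:
        return (
            self.facilitation_level
            if self.facilitation_level is not None
            else self.barrier_level
        )

    def __repr__(self) -> str:
        return f"Influence({self.short_name})"


def add_factor(
    model: Model,
    kind: FactorKind,
    label: str,
    code: Optional[Union[str, ICFCode]] = None,
    short_name: Optional[str] = None,
) -> ContextualFactor:
    """Register a contextual factor with the model.

    Personal factors are accepted as influencers (the Influence relation
    references the generic ContextualFactor class) but carry no code.
    """
    icf_code: Optional[ICFCode] = None
    if kind is FactorKind.ENVIRONMENTAL:
        if code is None:
            raise ModelError("environmental factors require an e-code")
        icf_code = parse_code(code) if isinstance(code, str) else code
        if icf_code.component is not Component.ENVIRONMENTAL_FACTORS:
            raise ModelError(f"{icf_code} is not an environmental-factor code")
    elif code is not None:
        raise ModelError("personal factors carry no ICF code")
    factor = ContextualFactor(
        kind=kind,
        label=label,
        short_name=model.claim_name(short_name or slugify(label)),
        code=icf_code,
    )
    model.factors.append(factor)
    return factor


def component_of(
    model: Model, hs: HealthState, component: Component
) -> InfluenceableComponent:
    """The convention-2 handle for one component of a health state.

    One handle exists per (state, component) pair; repeated calls
    return the same individual.
    """
    if component is Component.ENVIRONMENTAL_FACTORS:
        raise ModelError("only health-domain components can be influenced")
    for inf in model.influences:
        t = inf.target
        if (
            isinstance(t, InfluenceableComponent)
            and t.health_state is hs
            and t.component is component
        ):
            return t
    return InfluenceableComponent(
        health_state=hs,
        component=component,
        short_name=model.claim_name(
            f"{hs.short_name}_{component.class_name.lower()}"
        ),
    )


def add_influence(
    model: Model,
    target: InfluenceTarget,
    factor: ContextualFactor,
    polarity: Polarity,
    level: QualifierValue,
    manner: Optional[InfluencingManner] = None,
    short_name: Optional[str] = None,
) -> Influence:
    """Create an Influence linking ``factor`` to ``target``.

    The level must come from the scale matching the polarity:
    Facilitation values for facilitation, Hindrance values for
    hindrance.  The inverse relations (facilitates / hinders /
    influences) are derivable and emitted as schema axioms on export.
    """
    if target is None or factor is None:
        raise ModelError("influence requires both a target and a factor")
    if polarity is Polarity.FACILITATION:
        if level not in FACILITATION:
            raise ModelError(
                f"{level} is not a Facilitation value (polarity mismatch)"
            )
    else:
        if level not in HINDRANCE:
            raise ModelError(
                f"{level} is not a Hindrance value (polarity mismatch)"
            )
    target_name = getattr(target, "short_name", None)
    if target_name is None:
        raise ModelError(f"invalid influence target {target!r}")
    name = (
        model.claim_name(short_name)
        if short_name
        else model._auto_name(f"{target_name}_{factor.short_name.lower()}")
    )
    inf = Influence(
        factor=factor,
        target=target,
        short_name=name,
        facilitation_level=level if polarity is Polarity.FACILITATION else None,
        barrier_level=level if polarity is Polarity.HINDRANCE else None,
        manner=manner,
    )
    model.influences.append(inf)
    return inf


def convention_of(inf: Influence) -> int:
    """Which ICF coding convention the influence realizes (1, 2 or 3)."""
    if isinstance(inf.target, HealthState):
        return 1
    if isinstance(inf.target, InfluenceableComponent):
        return 2
    if isinstance(inf.target, QualifiedActivity):
        return 3
    raise ModelError(f"influence {inf.short_name} has an invalid target")


def classify_influence(inf: Influence) -> InfluenceClass:
    """Defined-class membership: Facilitator iff related via
    facilitatedBy, Barrier iff via hindrancedBy."""
    pol = inf.polarity
    if pol is Polarity.FACILITATION:
        return InfluenceClass.FACILITATOR
    if pol is Polarity.HINDRANCE:
        return InfluenceClass.BARRIER
    raise ModelError(
        f"influence {inf.short_name} has no single polarity; run validation"
    )


def influencing_factors(model: Model) -> set:
    """The defined class InfluencingFactor: contextual factors that
    appear as the factor of at least one influence."""
    return {inf.factor for inf in model.influences if inf.factor is not None}
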