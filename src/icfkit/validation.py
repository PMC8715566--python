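"""Consistency checking of a model against the formalized constraints.

The checks mirror the OWL axioms the export carries: disjointness of
sibling classes that implement a mutually exclusive classification,
functional/exact cardinalities of the n-ary relation slots, and
domain/range constraints of the object properties.  Checking is native
and deliberately shallow — full description-logic reasoning is out of
scope; exporting to OWL lets users run an external reasoner.

All violations are reported at once (never fail-fast) so that a model
can be repaired in one iteration.  Disjointness and cardinality
breaches are errors; an unregistered code is only a warning, because
the category registry is partial by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .codes import CategoryNode, Component
from .healthstate import HealthState, LifeSituation, Model, QualifiedActivity
from .influence import ContextualFactor, FactorKind, InfluenceableComponent
from .qualifiers import DIFFICULTY, FACILITATION, HINDRANCE

__all__ = [
    "Violation",
    "ValidationReport",
    "RULES",
    "check_disjointness",
    "check_cardinality",
    "check_domain_range",
    "check_registry",
    "validate",
]

ERROR = "error"
WARNING = "warning"

#: Rule identifiers, one per enforced constraint.
RULES = (
    "disjoint.class-membership",
    "card.qa-health-state",
    "card.state-subject",
    "card.influence-factor",
    "card.influence-target",
    "card.influence-polarity",
    "dr.difficulty-scale",
    "dr.level-scale",
    "dr.activity-component",
    "dr.factor-code",
    "dr.destination-range",
    "registry.unregistered-code",
)

#: Sibling classes implementing mutually exclusive classifications.
DISJOINT_PAIRS = (
    ("EnvironmentalFactor", "PersonalFactor"),
    ("ContextualFactor", "HealthDomain"),
    ("ActivityAndParticipation", "BodyFunction"),
    ("ActivityAndParticipation", "BodyStructure"),
    ("BodyFunction", "BodyStructure"),
)


@dataclass(frozen=True)
class Violation:
    rule: str
    severity: str
    entity: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.rule} @ {self.entity}: {self.message}"


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(v.severity == ERROR for v in self.violations)

    def errors(self) -> list:
        return [v for v in self.violations if v.severity == ERROR]

    def warnings(self) -> list:
        return [v for v in self.violations if v.severity == WARNING]

    def to_text(self) -> str:
        if not self.violations:
            return "validation passed: no violations\n"
        lines = [str(v) for v in self.violations]
        verdict = "passed" if self.passed else "FAILED"
        lines.append(
            f"validation {verdict}: {len(self.errors())} error(s), "
            f"{len(self.warnings())} warning(s)"
        )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "violations": [
                {
                    "rule": v.rule,
                    "severity": v.severity,
                    "entity": v.entity,
                    "message": v.message,
                }
                for v in self.violations
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _name(entity) -> str:
    return getattr(entity, "short_name", None) or getattr(entity, "key", repr(entity))


def _intrinsic_types(entity) -> set:
    if isinstance(entity, ContextualFactor):
        kind = (
            "EnvironmentalFactor"
            if entity.kind is FactorKind.ENVIRONMENTAL
            else "PersonalFactor"
        )
        return {"ContextualFactor", kind}
    if isinstance(entity, CategoryNode):
        return {"ICFCategory", entity.component.class_name, entity.component.group}
    if isinstance(entity, QualifiedActivity):
        return {"QualifiedActivity"}
    if isinstance(entity, HealthState):
        return {"HealthState"}
    if isinstance(entity, LifeSituation):
        return {"LifeSituation"}
    return set()


def check_disjointness(model: Model) -> list:
    """Flag entities asserted into two disjoint classes."""
    out = []
    seen: dict[int, object] = {}
    for factor in model.factors:
        seen.setdefault(id(factor), factor)
    for qa in model.qualified_activities():
        seen.setdefault(id(qa.activity), qa.activity)
    for entity, _ in model.extra_types:
        seen.setdefault(id(entity), entity)
    extra: dict[int, set] = {}
    for entity, cls in model.extra_types:
        extra.setdefault(id(entity), set()).add(cls)
    for entity in seen.values():
        types = _intrinsic_types(entity) | extra.get(id(entity), set())
        # superclass closure for asserted subclasses
        if types & {"EnvironmentalFactor", "PersonalFactor"}:
            types.add("ContextualFactor")
        if types & {"ActivityAndParticipation", "BodyFunction", "BodyStructure"}:
            types.add("HealthDomain")
        for a, b in DISJOINT_PAIRS:
            if a in types and b in types:
                out.append(
                    Violation(
                        "disjoint.class-membership",
                        ERROR,
                        _name(entity),
                        f"member of disjoint classes {a} and {b}",
                    )
                )
    return out


def check_cardinality(model: Model) -> list:
    """Enforce the exact-1 and 0..1 multiplicities of the n-ary slots."""
    out = []
    owner: dict[int, HealthState] = {}
    for hs in model.health_states:
        if hs.subject is None:
            out.append(
                Violation(
                    "card.state-subject",
                    ERROR,
                    hs.short_name,
                    "health state must have exactly one subject",
                )
            )
        for qa in hs.parts:
            if id(qa) in owner:
                out.append(
                    Violation(
                        "card.qa-health-state",
                        ERROR,
                        qa.short_name,
                        f"claimed by both {owner[id(qa)].short_name} "
                        f"and {hs.short_name}",
                    )
                )
            else:
                owner[id(qa)] = hs
            if qa.health_state is not hs and id(qa) in owner and owner[id(qa)] is hs:
                out.append(
                    Violation(
                        "card.qa-health-state",
                        ERROR,
                        qa.short_name,
                        "partOf back-reference does not match containing state",
                    )
                )
    for inf in model.influences:
        if inf.factor is None:
            out.append(
                Violation(
                    "card.influence-factor",
                    ERROR,
                    inf.short_name,
                    "influence must have exactly one factor",
                )
            )
        if inf.target is None:
            out.append(
                Violation(
                    "card.influence-target",
                    ERROR,
                    inf.short_name,
                    "influence must have exactly one target",
                )
            )
        has_f = inf.facilitation_level is not None
        has_b = inf.barrier_level is not None
        if has_f == has_b:  # both or neither
            out.append(
                Violation(
                    "card.influence-polarity",
                    ERROR,
                    inf.short_name,
                    "exactly one of facilitationLevel/barrierLevel required",
                )
            )
    return out


def check_domain_range(model: Model) -> list:
    """Domain/range constraints of the object properties."""
    out = []
    for qa in model.qualified_activities():
        for slot, qv in (("performance", qa.performance), ("capacity", qa.capacity)):
            if qv is not None and qv not in DIFFICULTY:
                out.append(
                    Violation(
                        "dr.difficulty-scale",
                        ERROR,
                        qa.short_name,
                        f"{slot} value {qv} is not from the Difficulty scale",
                    )
                )
        if qa.activity.component is not Component.ACTIVITIES_AND_PARTICIPATION:
            out.append(
                Violation(
                    "dr.activity-component",
                    ERROR,
                    qa.short_name,
                    f"activity {qa.activity.key} is not an A&P category",
                )
            )
        if qa.destination is not None and not isinstance(
            qa.destination, LifeSituation
        ):
            out.append(
                Violation(
                    "dr.destination-range",
                    ERROR,
                    qa.short_name,
                    "destination must be a LifeSituation",
                )
            )
    for inf in model.influences:
        if inf.facilitation_level is not None and inf.facilitation_level not in FACILITATION:
            out.append(
                Violation(
                    "dr.level-scale",
                    ERROR,
                    inf.short_name,
                    f"facilitationLevel {inf.facilitation_level} is not a "
                    "Facilitation value",
                )
            )
        if inf.barrier_level is not None and inf.barrier_level not in HINDRANCE:
            out.append(
                Violation(
                    "dr.level-scale",
                    ERROR,
                    inf.short_name,
                    f"barrierLevel {inf.barrier_level} is not a Hindrance value",
                )
            )
    for factor in model.factors:
        if factor.kind is FactorKind.ENVIRONMENTAL:
            bad = factor.code is None or (
                factor.code.component is not Component.ENVIRONMENTAL_FACTORS
            )
            if bad:
                out.append(
                    Violation(
                        "dr.factor-code",
                        ERROR,
                        factor.short_name,
                        "environmental factor requires a valid e-code",
                    )
                )
        elif factor.code is not None:
            out.append(
                Violation(
                    "dr.factor-code",
                    ERROR,
                    factor.short_name,
                    "personal factor must not carry an ICF code",
                )
            )
    return out


def check_registry(model: Model) -> list:
    """Warn about codes absent from the (partial) registry."""
    out = []
    for qa in model.qualified_activities():
        if not model.registry.is_registered(qa.activity.key):
            out.append(
                Violation(
                    "registry.unregistered-code",
                    WARNING,
                    qa.short_name,
                    f"activity code {qa.activity.key} is not registered",
                )
            )
    for factor in model.factors:
        if factor.code is not None and not model.registry.is_registered(factor.code):
            out.append(
                Violation(
                    "registry.unregistered-code",
                    WARNING,
                    factor.short_name,
                    f"factor code {factor.code} is not registered",
                )
            )
    return out


def validate(model: Model) -> ValidationReport:
    """Run every rule; idempotent and side-effect free.

    Violations are sorted by (rule, entity, message) so reports are
    deterministic regardless of model construction order.
    """
    violations = (
        check_disjointness(model)
        + check_cardinality(model)
        + check_domain_range(model)
        + check_registry(model)
    )
    violations.sort(key=lambda v: (v.rule, v.entity, v.message))
    return ValidationReport(violations)
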