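"""The Health States bounded context.

A health state is a snapshot of the functioning of one human being at
assessment time.  Each assessed action is reified as a
``QualifiedActivity`` — the n-ary relation ("introducing a new class
for a relation" pattern) tying together the activity category, an
optional performance difficulty, an optional capacity difficulty and an
optional destination life situation.  Qualified activities aggregate
into their health state through ``partOf`` with multiplicity exactly
one, and the agent of an activity is reached *indirectly* through the
health state's subject: there is deliberately no direct activity→agent
link.

Participation is instance-level, never category-level: the ICF gives a
single list of actions, and an action counts as participation for a
particular subject exactly when its qualified activity has a
destination toward a life situation.  ``QualifiedParticipativeActivity``
is therefore a *defined* class (membership inferred from the
destination link) over the *primitive* ``QualifiedActivity``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .codes import (
    CategoryNode,
    CategoryRegistry,
    Component,
    ICFCode,
    default_registry,
    parse_code,
)
from .qualifiers import DIFFICULTY, QualifierValue

__all__ = [
    "Human",
    "LifeSituation",
    "HealthState",
    "QualifiedActivity",
    "Model",
    "ModelError",
    "slugify",
    "new_health_state",
    "add_qualified_activity",
    "set_destination",
    "is_participation",
    "agent_of",
]


class ModelError(ValueError):
    """Raised on operations that would break a model invariant."""


def slugify(text: str) -> str:
    """Deterministic short-name fragment from a free-text label."""
    slug = re.sub(r"[^A-Za-z0-9]+", "_", text.strip()).strip("_")
    return slug or "x"


@dataclass(eq=False)
class Human:
    """A subject under assessment (an agent; all agents here are human)."""

    name: str
    short_name: str


@dataclass(eq=False)
class LifeSituation:
    """A social setting an action is directed at.

    Deliberately a bare labeled individual: the ICF gives the term no
    further structure, so no taxonomy is imposed on it.
    """

    label: str
    short_name: str


@dataclass(eq=False)
class QualifiedActivity:
    """The reified assessment of one action within one health state."""

    activity: CategoryNode
    health_state: Optional["HealthState"]
    short_name: str
    activity_instance: str  # short name of the category individual
    performance: Optional[QualifierValue] = None
    capacity: Optional[QualifierValue] = None
    destination: Optional[LifeSituation] = None

    def __repr__(self) -> str:
        return f"QualifiedActivity({self.short_name})"


@dataclass(eq=False)
class HealthState:
    """All assessments of one subject at one point in time."""

    subject: Optional[Human]
    label: str
    short_name: str
    parts: list = field(default_factory=list)

    def __repr__(self) -> str:
        return f"HealthState({self.short_name})"


class Model:
    """A container for one or more encoded assessments.

    Holds the humans, health states, qualified activities, life
    situations, contextual factors and influences of a working set,
    plus the category registry they are resolved against.  The
    ``extra_types`` list carries additional class assertions (used by
    consistency checking and by Turtle import); a well-formed model has
    none.
    """

    def __init__(self, registry: Optional[CategoryRegistry] = None):
        self.registry = registry if registry is not None else default_registry()
        self.humans: list[Human] = []
        self.health_states: list[HealthState] = []
        self.life_situations: list[LifeSituation] = []
        self.factors: list = []  # ContextualFactor, managed by icfkit.influence
        self.influences: list = []  # Influence, managed by icfkit.influence
        self.extra_types: list[tuple[object, str]] = []
        self._short_names: set[str] = set()

    # -- naming -------------------------------------------------------

    def claim_name(self, name: str) -> str:
        if name in self._short_names:
            raise ModelError(f"short name {name!r} already in use")
        self._short_names.add(name)
        return name

    def _auto_name(self, base: str) -> str:
        n = 1
        while f"{base}_{n}" in self._short_names:
            n += 1
        return self.claim_name(f"{base}_{n}")

    # -- entity creation ---------------------------------------------

    def add_human(self, name: str, short_name: Optional[str] = None) -> Human:
        human = Human(name, self.claim_name(short_name or slugify(name)))
        self.humans.append(human)
        return human

    def add_life_situation(
        self, label: str, short_name: Optional[str] = None
    ) -> LifeSituation:
        ls = LifeSituation(label, self.claim_name(short_name or slugify(label)))
        self.life_situations.append(ls)
        return ls

    def new_health_state(
        self, subject: Human, label: str, short_name: Optional[str] = None
    ) -> HealthState:
        if subject not in self.humans:
            raise ModelError(f"unknown subject {subject!r}")
        name = (
            self.claim_name(short_name)
            if short_name
            else self._auto_name(f"{subject.short_name}_state")
        )
        hs = HealthState(subject=subject, label=label, short_name=name)
        self.health_states.append(hs)
        return hs

    def resolve_category(self, code: Union[str, ICFCode, CategoryNode]) -> CategoryNode:
        """Resolve a code to a registry node, or build an unregistered
        placeholder node (the registry is partial by design)."""
        if isinstance(code, CategoryNode):
            return code
        icf_code = parse_code(code) if isinstance(code, str) else code
        if self.registry.is_registered(icf_code):
            return self.registry.get(icf_code)
        return CategoryNode(code=icf_code, title=str(icf_code), kind="category")

    def add_qualified_activity(
        self,
        hs: HealthState,
        code: Union[str, ICFCode, CategoryNode],
        performance: Optional[QualifierValue] = None,
        capacity: Optional[QualifierValue] = None,
        short_name: Optional[str] = None,
        activity_instance: Optional[str] = None,
    ) -> QualifiedActivity:
        """Attach a new qualified activity to ``hs``.

        ``code`` must be an Activities & Participation (d) category;
        performance and capacity, when given, must be Difficulty-scale
        values.  The two qualifiers are independent: setting one never
        touches the other.
        """
        if hs not in self.health_states:
            raise ModelError(f"health state {hs!r} is not in this model")
        node = self.resolve_category(code)
        if node.component is not Component.ACTIVITIES_AND_PARTICIPATION:
            raise ModelError(
                f"{node.key} is not an Activities & Participation category"
            )
        for qv in (performance, capacity):
            if qv is not None and qv not in DIFFICULTY:
                raise ModelError(
                    f"{qv} is not a Difficulty-scale value"
                )
        instance = activity_instance or slugify(node.title).capitalize()
        name = (
            self.claim_name(short_name)
            if short_name
            else self._auto_name(f"{hs.short_name}_{instance.lower()}")
        )
        qa = QualifiedActivity(
            activity=node,
            health_state=hs,
            short_name=name,
            activity_instance=instance,
            performance=performance,
            capacity=capacity,
        )
        hs.parts.append(qa)
        return qa

    # -- queries ------------------------------------------------------

    def qualified_activities(self) -> Iterator[QualifiedActivity]:
        for hs in self.health_states:
            yield from hs.parts

    def participations(self) -> list[QualifiedActivity]:
        """The defined class QualifiedParticipativeActivity."""
        return [qa for qa in self.qualified_activities() if is_participation(qa)]

    def find(self, short_name: str):
        """Look any entity up by its short name."""
        pools: list = [self.humans, self.health_states, self.life_situations,
                       self.factors, self.influences]
        for pool in pools:
            for ent in pool:
                if ent.short_name == short_name:
                    return ent
        for qa in self.qualified_activities():
            if qa.short_name == short_name:
                return qa
        raise ModelError(f"no entity named {short_name!r}")


# -- module-level operation forms (the spec'd API surface) -------------


def new_health_state(
    model: Model, subject: Human, label: str, short_name: Optional[str] = None
) -> HealthState:
    return model.new_health_state(subject, label, short_name)


def add_qualified_activity(
    model: Model,
    hs: HealthState,
    code,
    performance: Optional[QualifierValue] = None,
    capacity: Optional[QualifierValue] = None,
    **kwargs,
) -> QualifiedActivity:
    return model.add_qualified_activity(hs, code, performance, capacity, **kwargs)


def set_destination(
    qa: QualifiedActivity, situation: LifeSituation, replace: bool = False
) -> QualifiedActivity:
    """Direct ``qa`` at a life situation, making it a participation.

    The destination has multiplicity 0..1: overwriting an existing
    destination requires ``replace=True``.
    """
    if qa.destination is not None and not replace:
        raise ModelError(
            f"{qa.short_name} already has destination "
            f"{qa.destination.short_name}; pass replace=True to overwrite"
        )
    qa.destination = situation
    return qa


def is_participation(qa: QualifiedActivity) -> bool:
    """Defined-class membership: QualifiedActivity ⊓ ∃destination.LifeSituation."""
    return qa.destination is not None


def agent_of(qa: QualifiedActivity) -> Human:
    """The subject of ``qa``'s health state (the indirect agent link)."""
    if qa.health_state is None or qa.health_state.subject is None:
        raise ModelError(f"{qa.short_name} is not attached to a subject's state")
    return qa.health_state.subject
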