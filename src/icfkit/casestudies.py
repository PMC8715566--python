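"""Categorical profiles, worked-example fixtures and synthetic models.

An ICF categorical profile is a table of code + qualifier pairs, often
split into a "problem" section (d-codes with difficulty digits) and a
"facilitator/barrier" section (e-codes with facilitation or hindrance
digits).  :func:`read_profile` parses such CSVs, :func:`encode_profile`
turns the rows into a validated model, and :func:`fixtures` ships four
worked case studies whose individual short names follow the
``Peter_state_1_changing_position_1`` naming style:

* ``e_case`` — a single unqualified d7202 activity (subject "E.");
* ``peter``  — four mobility activities with difficulty digits 1/2/4/3;
* ``conrad`` — four activities (digits 0/2/3/4) plus three
  environmental factors coded with convention 1: e1151 +3, e155 barrier
  3, e580 +2;
* ``john``   — a convention-3 facilitator: lifting with severe
  difficulty, eased by ibuprofen (e1101) to an unspecified ("some")
  extent.

:func:`generate_synthetic` produces seeded, reproducible models for the
three validation scenarios (activities alone, participation, activities
with environmental factors) and can inject exactly one consistency
fault per validation rule for oracle testing.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
from dataclasses import dataclass, field
from random import Random
from typing import Iterable, Optional, Sequence, Union

from .codes import Component, parse_code
from .healthstate import Human, Model, ModelError, new_health_state, set_destination
from .influence import (
    FactorKind,
    InfluencingManner,
    Polarity,
    add_factor,
    add_influence,
    component_of,
)
from .qualifiers import (
    DIFFICULTY,
    FACILITATION,
    HINDRANCE,
    SuffixKind,
    parse_qualifier_suffix,
)

__all__ = [
    "ProfileRow",
    "ProfileError",
    "SyntheticSpec",
    "FAULTS",
    "read_profile",
    "encode_profile",
    "fixtures",
    "generate_synthetic",
    "profile_path",
]


class ProfileError(ValueError):
    """A malformed profile row, reported with its location."""


@dataclass(frozen=True)
class ProfileRow:
    """One code + qualifier pair of a categorical profile."""

    code: str
    qualifier: str
    section: Optional[str] = None  # "problem" | "facilitator" | "barrier"


_SECTIONS = {None, "", "problem", "facilitator", "barrier"}


def read_profile(source) -> list[ProfileRow]:
    """Parse profile rows from a CSV path, stream or record iterable.

    The CSV has a header ``code,qualifier[,section]``.  Every code must
    parse and every qualifier suffix must resolve against the code's
    component; errors carry the 1-based data row number.
    """
    if hasattr(source, "read"):
        records = list(csv.DictReader(source))
    elif isinstance(source, (str,)) or hasattr(source, "open"):
        with open(source, encoding="utf-8", newline="") as fh:
            records = list(csv.DictReader(fh))
    else:
        records = [dict(r) for r in source]

    rows: list[ProfileRow] = []
    for i, rec in enumerate(records, start=1):
        code_text = (rec.get("code") or "").strip()
        qual_text = (rec.get("qualifier") or "").strip()
        section = (rec.get("section") or "").strip().lower() or None
        try:
            code = parse_code(code_text)
            if qual_text:
                kind, _ = parse_qualifier_suffix(qual_text, code.component)
                if section == "facilitator" and kind is not SuffixKind.FACILITATION:
                    raise ProfileError("facilitator section expects a '+' suffix")
                if section == "barrier" and kind is not SuffixKind.HINDRANCE:
                    raise ProfileError("barrier section expects a '.' suffix on an e-code")
        except ValueError as exc:
            raise ProfileError(f"row {i} ({code_text!r},{qual_text!r}): {exc}") from None
        if section not in _SECTIONS:
            raise ProfileError(f"row {i}: unknown section {section!r}")
        rows.append(ProfileRow(code_text, qual_text, section))
    return rows


def encode_profile(
    rows: Sequence[ProfileRow],
    subject: Union[str, Human],
    label: str,
    ef_convention: int = 1,
    registry=None,
    model: Optional[Model] = None,
) -> Model:
    """Encode profile rows as one health state in a (new) model.

    Each d-row becomes a qualified activity whose difficulty digit maps
    to the *performance* qualifier; capacity stays unset.  Each e-row
    becomes an influence attached per ``ef_convention``: 1 → the whole
    health state (the default, as in the Conrad example), 2 → the
    Activities & Participation component of the state, 3 → the most
    recent preceding qualified activity.
    """
    if ef_convention not in (1, 2, 3):
        raise ProfileError(f"unknown coding convention {ef_convention}")
    if model is None:
        model = Model(registry=registry)
    human = subject if isinstance(subject, Human) else model.add_human(subject)
    hs = new_health_state(model, human, label)
    last_qa = None
    for i, row in enumerate(rows, start=1):
        code = parse_code(row.code)
        if code.component is Component.ACTIVITIES_AND_PARTICIPATION:
            performance = None
            if row.qualifier:
                kind, qv = parse_qualifier_suffix(row.qualifier, code.component)
                if kind is not SuffixKind.DIFFICULTY:
                    raise ProfileError(
                        f"row {i}: d-code {row.code} cannot take a "
                        f"{kind.value} qualifier"
                    )
                performance = qv
            last_qa = model.add_qualified_activity(hs, code, performance=performance)
        elif code.component is Component.ENVIRONMENTAL_FACTORS:
            if not row.qualifier:
                raise ProfileError(f"row {i}: e-code {row.code} requires a qualifier")
            kind, qv = parse_qualifier_suffix(row.qualifier, code.component)
            polarity = (
                Polarity.FACILITATION
                if kind is SuffixKind.FACILITATION
                else Polarity.HINDRANCE
            )
            node = model.resolve_category(code)
            factor = add_factor(
                model, FactorKind.ENVIRONMENTAL, node.title, code=code
            )
            if ef_convention == 1:
                target = hs
            elif ef_convention == 2:
                target = component_of(
                    model, hs, Component.ACTIVITIES_AND_PARTICIPATION
                )
            else:
                if last_qa is None:
                    raise ProfileError(
                        f"row {i}: convention 3 needs a preceding d-row"
                    )
                target = last_qa
            add_influence(model, target, factor, polarity, qv)
        else:
            raise ProfileError(
                f"row {i}: component {code.component.letter!r} is out of scope"
            )
    return model


def profile_path(name: str):
    """Path to a shipped profile CSV (``peter`` or ``conrad``)."""
    return importlib.resources.files("icfkit").joinpath(f"data/profiles/{name}.csv")


# -- worked-example fixtures ------------------------------------------


def _e_case() -> Model:
    model = Model()
    e = model.add_human("E.", short_name="E")
    hs = model.new_health_state(
        e, "E.'s health state 2020_june_6", short_name="E_state_1"
    )
    model.add_qualified_activity(
        hs,
        "d7202",
        short_name="E_state_1_reacting_1",
        activity_instance="Reacting",
    )
    return model


def _peter() -> Model:
    model = Model()
    peter = model.add_human("Peter Taylor", short_name="Peter")
    hs = model.new_health_state(
        peter, "Peter's health state 2021_mar_17", short_name="Peter_state_1"
    )
    for code, digit, instance, short in [
        ("d410", 1, "Changing_position", "Peter_state_1_changing_position_1"),
        ("d4200", 2, "Transferring", "Peter_state_1_transferring_1"),
        ("d440", 4, "Fine_hand_use", "Peter_state_1_fine_hand_use_1"),
        ("d445", 3, "Hand_arm_use", "Peter_state_1_hand_arm_use_1"),
    ]:
        model.add_qualified_activity(
            hs,
            code,
            performance=DIFFICULTY.value(digit),
            short_name=short,
            activity_instance=instance,
        )
    return model


def _conrad() -> Model:
    model = Model()
    conrad = model.add_human("Conrad", short_name="Conrad")
    hs = model.new_health_state(
        conrad, "Conrad's health state", short_name="Conrad_state_1"
    )
    for code, digit, instance in [
        ("d4153", 0, "Maintaining_sitting"),
        ("d4154", 2, "Maintaining_standing"),
        ("d465", 3, "Moving_with_equipment"),
        ("d850", 4, "Remunerative_employment"),
    ]:
        model.add_qualified_activity(
            hs, code, performance=DIFFICULTY.value(digit), activity_instance=instance
        )
    # environmental factors, first coding convention: coded on the state
    for code, label, short, polarity, digit in [
        ("e1151", "Assistive products for personal mobility",
         "Assistive_products_1", Polarity.FACILITATION, 3),
        ("e155", "Design, construction of building for private use",
         "Building_design_1", Polarity.HINDRANCE, 3),
        ("e580", "Health services, systems and policies",
         "Health_services_1", Polarity.FACILITATION, 2),
    ]:
        factor = add_factor(
            model, FactorKind.ENVIRONMENTAL, label, code=code, short_name=short
        )
        scale = FACILITATION if polarity is Polarity.FACILITATION else HINDRANCE
        add_influence(model, hs, factor, polarity, scale.value(digit))
    return model


def _john() -> Model:
    model = Model()
    john = model.add_human("John Smith", short_name="John")
    hs = model.new_health_state(
        john, "John's state 2018_feb_4", short_name="John_state_2"
    )
    qa = model.add_qualified_activity(
        hs,
        "d4300",
        performance=DIFFICULTY.value(3),
        short_name="John_state_2_lifting_1",
        activity_instance="Lifting_1",
    )
    ibuprofen = add_factor(
        model,
        FactorKind.ENVIRONMENTAL,
        "Ibuprofen",
        code="e1101",
        short_name="Ibuprofen_1",
    )
    # third coding convention: the influence targets the activity itself
    add_influence(
        model,
        qa,
        ibuprofen,
        Polarity.FACILITATION,
        FACILITATION.value(8),  # "some": the sentence leaves the extent vague
        short_name="John_state_2_lifting_1_ibuprofen_1",
    )
    return model


def fixtures() -> dict[str, Model]:
    """The four worked case studies as fresh models."""
    return {
        "e_case": _e_case(),
        "peter": _peter(),
        "conrad": _conrad(),
        "john": _john(),
    }


# -- synthetic generation ---------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for one synthetic model.

    ``n_influences`` gives the number of influences per coding
    convention (1, 2, 3).  ``faults`` names validation rules to break,
    one injected violation each (see :data:`FAULTS`).
    """

    n_activities: int = 10
    n_influences: tuple[int, int, int] = (2, 1, 1)
    participation_rate: float = 0.3
    seed: int = 0
    faults: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_activities < 0 or any(n < 0 for n in self.n_influences):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.participation_rate <= 1.0:
            raise ValueError("participation_rate must be within [0, 1]")


def generate_synthetic(spec: SyntheticSpec, registry=None) -> Model:
    """A seeded, reproducible model following ``spec``.

    Activities draw random categories and difficulty digits 0-4; a
    ``participation_rate`` share of them receive a destination life
    situation; influences are spread over the requested conventions
    with random polarity, matching level and a random manner.  Without
    fault injections the model validates by construction.
    """
    rng = Random(spec.seed)
    model = Model(registry=registry)
    subject = model.add_human(f"Synthetic subject {spec.seed}", short_name="Subject")
    hs = model.new_health_state(subject, f"synthetic state seed={spec.seed}")

    d_codes = sorted(
        n.key
        for n in model.registry.categories(Component.ACTIVITIES_AND_PARTICIPATION)
        if n.kind == "category"
    )
    e_codes = sorted(
        n.key
        for n in model.registry.categories(Component.ENVIRONMENTAL_FACTORS)
        if n.kind == "category"
    )
    difficulty_digits = [0, 1, 2, 3, 4]

    qas = []
    for _ in range(spec.n_activities):
        qa = model.add_qualified_activity(
            hs,
            rng.choice(d_codes),
            performance=DIFFICULTY.value(rng.choice(difficulty_digits)),
            capacity=(
                DIFFICULTY.value(rng.choice(difficulty_digits))
                if rng.random() < 0.5
                else None
            ),
        )
        qas.append(qa)
        if rng.random() < spec.participation_rate:
            situation = model.add_life_situation(
                f"life situation {len(model.life_situations) + 1}"
            )
            set_destination(qa, situation)

    for convention, count in zip((1, 2, 3), spec.n_influences):
        for _ in range(count):
            if convention == 3 and not qas:
                continue  # convention 3 needs an activity to attach to
            kind = (
                FactorKind.ENVIRONMENTAL
                if rng.random() < 0.8
                else FactorKind.PERSONAL
            )
            factor = add_factor(
                model,
                kind,
                f"factor {len(model.factors) + 1}",
                code=rng.choice(e_codes)
                if kind is FactorKind.ENVIRONMENTAL
                else None,
            )
            polarity = (
                Polarity.FACILITATION if rng.random() < 0.5 else Polarity.HINDRANCE
            )
            scale = FACILITATION if polarity is Polarity.FACILITATION else HINDRANCE
            level = scale.value(rng.choice([0, 1, 2, 3, 4, 8]))
            manner = (
                rng.choice(list(InfluencingManner)) if rng.random() < 0.5 else None
            )
            if convention == 1:
                target = hs
            elif convention == 2:
                target = component_of(
                    model, hs, Component.ACTIVITIES_AND_PARTICIPATION
                )
            else:
                target = rng.choice(qas)
            add_influence(model, target, factor, polarity, level, manner=manner)

    for fault in spec.faults:
        try:
            FAULTS[fault](model)
        except KeyError:
            raise ValueError(f"unknown fault {fault!r}") from None
    return model


# -- fault injectors: one per validation rule -------------------------


def _need(condition: bool, what: str) -> None:
    if not condition:
        raise ModelError(f"fault injection needs {what}")


def _first_qa(model: Model):
    qa = next(model.qualified_activities(), None)
    _need(qa is not None, "at least one qualified activity")
    return qa


def _first_influence(model: Model):
    _need(bool(model.influences), "at least one influence")
    return model.influences[0]


def _fault_disjoint(model: Model) -> None:
    qa = _first_qa(model)
    model.extra_types.append((qa.activity, "BodyFunction"))


def _fault_qa_two_states(model: Model) -> None:
    qa = _first_qa(model)
    second = model.new_health_state(model.humans[0], "duplicate-claim state")
    second.parts.append(qa)


def _fault_state_no_subject(model: Model) -> None:
    orphan = model.new_health_state(model.humans[0], "orphan state")
    orphan.subject = None


def _fault_influence_no_factor(model: Model) -> None:
    _first_influence(model).factor = None


def _fault_influence_no_target(model: Model) -> None:
    _first_influence(model).target = None


def _fault_double_polarity(model: Model) -> None:
    inf = _first_influence(model)
    if inf.facilitation_level is not None:
        inf.barrier_level = HINDRANCE.value(2)
    else:
        inf.facilitation_level = FACILITATION.value(2)


def _fault_difficulty_scale(model: Model) -> None:
    _first_qa(model).performance = HINDRANCE.value(2)


def _fault_level_scale(model: Model) -> None:
    inf = _first_influence(model)
    if inf.facilitation_level is not None:
        inf.facilitation_level = HINDRANCE.value(2)
    else:
        inf.barrier_level = FACILITATION.value(2)


def _fault_activity_component(model: Model) -> None:
    _first_qa(model).activity = model.resolve_category("e155")


def _fault_factor_code(model: Model) -> None:
    from .influence import ContextualFactor  # cycle-safe local import

    for factor in model.factors:
        if factor.kind is FactorKind.ENVIRONMENTAL:
            factor.code = None
            return
    bad = ContextualFactor(
        kind=FactorKind.ENVIRONMENTAL,
        label="codeless factor",
        short_name=model.claim_name("codeless_factor"),
        code=None,
    )
    model.factors.append(bad)


def _fault_destination_range(model: Model) -> None:
    _first_qa(model).destination = model.humans[0]


def _fault_unregistered_code(model: Model) -> None:
    model.add_qualified_activity(model.health_states[0], "d999")


#: rule id -> injector breaking exactly that rule once
FAULTS = {
    "disjoint.class-membership": _fault_disjoint,
    "card.qa-health-state": _fault_qa_two_states,
    "card.state-subject": _fault_state_no_subject,
    "card.influence-factor": _fault_influence_no_factor,
    "card.influence-target": _fault_influence_no_target,
    "card.influence-polarity": _fault_double_polarity,
    "dr.difficulty-scale": _fault_difficulty_scale,
    "dr.level-scale": _fault_level_scale,
    "dr.activity-component": _fault_activity_component,
    "dr.factor-code": _fault_factor_code,
    "dr.destination-range": _fault_destination_range,
    "registry.unregistered-code": _fault_unregistered_code,
}
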