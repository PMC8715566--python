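"""ICF qualifier scales as closed enumerations of value individuals.

Qualifiers are the ICF's measurement instrument: predefined value sets
in which each value carries a digit code, a short description and
(optionally) a percentage range of extent.  The current ICF lists seven
qualifier names — impairment, nature of change, localization,
performance, capacity, barrier, facilitator — of which this toolkit
models the three value scales relevant to Activities & Participation
and Environmental Factors:

* ``Difficulty`` — used by both the performance and capacity qualifiers;
* ``Hindrance``  — the barrier qualifier's magnitude scale;
* ``Facilitation`` — the facilitator qualifier's magnitude scale.

Values are modelled as *individuals* of enumerated classes, never bare
literals: a literal cannot be the subject of further statements, while
an individual can later be grouped, annotated or counted.  Scales are
closed — the member set is fixed at construction and identical objects
are returned on every lookup (enumerated-class semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple, Union

import yaml

__all__ = [
    "ICF_QUALIFIER_NAMES",
    "GENERIC_PERCENT_RANGES",
    "QualifierValue",
    "QualifierScale",
    "QualifierError",
    "SuffixKind",
    "scale",
    "scale_names",
    "value",
    "parse_qualifier_suffix",
    "load_scales",
]

#: The seven qualifier names of the current ICF.
ICF_QUALIFIER_NAMES: Tuple[str, ...] = (
    "impairment",
    "nature of change",
    "localization",
    "performance",
    "capacity",
    "barrier",
    "facilitator",
)

#: The ICF generic scale's percentage ranges for digits 0-4.
GENERIC_PERCENT_RANGES: dict[int, Tuple[int, int]] = {
    0: (0, 4),
    1: (5, 24),
    2: (25, 49),
    3: (50, 95),
    4: (96, 100),
}


class QualifierError(ValueError):
    """Raised for unknown scales, values or malformed qualifier suffixes."""


@dataclass(frozen=True)
class QualifierValue:
    """One enumerated value of a qualifier scale.

    ``digit`` follows the ICF convention: 0-4 grade the extent, 8 marks
    an unspecified ("some") extent.  ``percent_range`` is the closed
    interval of extent percentages the digit covers, where defined.
    """

    scale_name: str
    digit: int
    label: str
    percent_range: Optional[Tuple[int, int]] = None

    def __str__(self) -> str:
        return f"{self.digit} {self.label} ({self.scale_name})"


class QualifierScale:
    """A closed, ordered enumeration of :class:`QualifierValue` members."""

    def __init__(self, name: str, values: Tuple[QualifierValue, ...]):
        digits = [v.digit for v in values]
        labels = [v.label for v in values]
        if len(set(digits)) != len(digits) or len(set(labels)) != len(labels):
            raise QualifierError(f"duplicate digit or label in scale {name}")
        for v in values:
            if v.digit not in (0, 1, 2, 3, 4, 8):
                raise QualifierError(f"digit {v.digit} outside ICF convention")
        self.name = name
        self.values: Tuple[QualifierValue, ...] = values
        self._by_digit = {v.digit: v for v in values}
        self._by_label = {v.label: v for v in values}

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, v: QualifierValue) -> bool:
        return self._by_digit.get(v.digit) is v

    def __repr__(self) -> str:
        return f"QualifierScale({self.name}, {len(self.values)} values)"

    def value(self, key: Union[int, str]) -> QualifierValue:
        """Look a member up by digit or by label; the two routes agree."""
        table = self._by_digit if isinstance(key, int) else self._by_label
        try:
            return table[key]
        except KeyError:
            raise QualifierError(
                f"no value {key!r} in the {self.name} scale"
            ) from None


def _build(name: str, labels: dict[int, str]) -> QualifierScale:
    return QualifierScale(
        name,
        tuple(
            QualifierValue(name, d, lbl, GENERIC_PERCENT_RANGES.get(d))
            for d, lbl in labels.items()
        ),
    )


# Module-level singletons give the closed-enumeration identity guarantee.
DIFFICULTY = _build(
    "Difficulty",
    {0: "no problem", 1: "mild", 2: "moderate", 3: "severe", 4: "complete",
     8: "not specified"},
)
HINDRANCE = _build(
    "Hindrance",
    {0: "no", 1: "mild", 2: "moderate", 3: "severe", 4: "complete", 8: "some"},
)
FACILITATION = _build(
    "Facilitation",
    {0: "no", 1: "mild", 2: "moderate", 3: "substantial", 4: "complete",
     8: "some"},
)

_SCALES = {s.name: s for s in (DIFFICULTY, HINDRANCE, FACILITATION)}


def scale_names() -> Tuple[str, ...]:
    return tuple(_SCALES)


def scale(name: str) -> QualifierScale:
    """Return the named scale (``Difficulty``, ``Hindrance`` or
    ``Facilitation``).  Case-insensitive.  Other ICF qualifier scales
    (impairment etc.) belong to the Body Functions/Structures scope and
    are rejected.
    """
    try:
        return _SCALES[name.capitalize()]
    except (KeyError, AttributeError):
        raise QualifierError(f"unknown qualifier scale {name!r}") from None


def value(scale_name: str, key: Union[int, str]) -> QualifierValue:
    """Convenience lookup: ``value("Facilitation", 3)`` → substantial."""
    return scale(scale_name).value(key)


class SuffixKind(Enum):
    DIFFICULTY = "difficulty"
    HINDRANCE = "hindrance"
    FACILITATION = "facilitation"


def parse_qualifier_suffix(text: str, component) -> tuple[SuffixKind, QualifierValue]:
    """Resolve a coded qualifier suffix against a code's component.

    ``".<d>"`` denotes a difficulty digit on d-codes and a hindrance
    (barrier) digit on e-codes; ``"+<d>"`` denotes facilitation and is
    only legal on e-codes.  ``component`` is a :class:`~icfkit.codes.Component`.
    """
    from .codes import Component  # local import avoids a cycle at import time

    text = text.strip()
    if len(text) != 2 or text[0] not in "+." or not text[1].isdigit():
        raise QualifierError(f"malformed qualifier suffix {text!r}")
    digit = int(text[1])
    if text[0] == "+":
        if component is not Component.ENVIRONMENTAL_FACTORS:
            raise QualifierError(
                "facilitation suffix '+' is only valid on e-codes"
            )
        kind, sc = SuffixKind.FACILITATION, FACILITATION
    elif component is Component.ENVIRONMENTAL_FACTORS:
        kind, sc = SuffixKind.HINDRANCE, HINDRANCE
    else:
        kind, sc = SuffixKind.DIFFICULTY, DIFFICULTY
    if digit not in sc._by_digit:
        raise QualifierError(
            f"digit {digit} outside the {sc.name} scale"
        )
    return kind, sc.value(digit)


def load_scales(path) -> dict[str, QualifierScale]:
    """Load localized label/range overrides from a YAML file.

    The file maps scale names to ``{digit: label}`` or
    ``{digit: [label, lo, hi]}`` entries; scales not mentioned keep
    their defaults.  The returned scales are new closed enumerations —
    the built-in singletons are never mutated.
    """
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh) or {}
    out: dict[str, QualifierScale] = {}
    for name, base in _SCALES.items():
        override = spec.get(name)
        if not override:
            out[name] = base
            continue
        values = []
        for v in base.values:
            entry = override.get(v.digit)
            if entry is None:
                values.append(v)
            elif isinstance(entry, str):
                values.append(QualifierValue(name, v.digit, entry, v.percent_range))
            else:
                label, lo, hi = entry
                values.append(QualifierValue(name, v.digit, label, (int(lo), int(hi))))
        out[name] = QualifierScale(name, tuple(values))
    return out
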