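"""ICF category codes and the classification-scheme registry.

The ICF identifies its classification units by alphanumeric codes: a
component letter (``b`` body functions, ``s`` body structures, ``d``
activities and participation, ``e`` environmental factors) followed by
one digit for a chapter, three for a second-level category, four for a
third-level and five for a fourth-level category.  Blocks (e.g.
``d330-d349``) are labeled code *ranges*, structural groupings rather
than codable units, and are represented here as range nodes.

The registry implements the ``ICFCategory`` side of the model: a partial,
loadable subset of the classification hierarchy.  It is partial by
design — operations work on any subset, and codes absent from the
registry are still parseable, merely unregistered.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Union

__all__ = [
    "Component",
    "Level",
    "ICFCode",
    "CodeRange",
    "CategoryNode",
    "CategoryRegistry",
    "ICFCodeError",
    "RegistryError",
    "parse_code",
    "parse_block",
    "parent_code",
    "load_registry",
    "load_registry_file",
    "default_registry",
]


class ICFCodeError(ValueError):
    """Raised for syntactically invalid ICF codes."""


class RegistryError(ValueError):
    """Raised when registry rows violate the hierarchy invariants."""


class Component(Enum):
    """The four ICF components, keyed by their code letter."""

    BODY_FUNCTIONS = "b"
    BODY_STRUCTURES = "s"
    ACTIVITIES_AND_PARTICIPATION = "d"
    ENVIRONMENTAL_FACTORS = "e"

    @property
    def letter(self) -> str:
        return self.value

    @property
    def group(self) -> str:
        """Top-level grouping: HealthDomain for b/s/d, ContextualFactor for e.

        Health domains and contextual factors are disjoint: a category in
        the health domain cannot also be a contextual factor.
        """
        if self is Component.ENVIRONMENTAL_FACTORS:
            return "ContextualFactor"
        return "HealthDomain"

    @property
    def class_name(self) -> str:
        return {
            Component.BODY_FUNCTIONS: "BodyFunction",
            Component.BODY_STRUCTURES: "BodyStructure",
            Component.ACTIVITIES_AND_PARTICIPATION: "ActivityAndParticipation",
            Component.ENVIRONMENTAL_FACTORS: "EnvironmentalFactor",
        }[self]


class Level(Enum):
    CHAPTER = 1
    SECOND = 3
    THIRD = 4
    FOURTH = 5

    @property
    def n_digits(self) -> int:
        return self.value


_LEVEL_BY_DIGITS = {lv.n_digits: lv for lv in Level}


@dataclass(frozen=True, order=True)
class ICFCode:
    """A single ICF category code, e.g. ``d410`` or ``e1151``."""

    component: Component
    digits: str

    def __post_init__(self) -> None:
        if not self.digits.isdigit():
            raise ICFCodeError(f"non-numeric digits in code: {self.digits!r}")
        if len(self.digits) not in _LEVEL_BY_DIGITS:
            raise ICFCodeError(
                f"invalid digit count {len(self.digits)} for code "
                f"{self.component.letter}{self.digits!r} (expected 1, 3, 4 or 5)"
            )

    @property
    def level(self) -> Level:
        return _LEVEL_BY_DIGITS[len(self.digits)]

    @property
    def chapter(self) -> "ICFCode":
        return ICFCode(self.component, self.digits[0])

    def __str__(self) -> str:
        return f"{self.component.letter}{self.digits}"


def parse_code(text: str) -> ICFCode:
    """Parse an ICF code string such as ``"d410"``.

    Rejects block/range notation (``d330-d349``); use :func:`parse_block`
    for that.  Raises :class:`ICFCodeError` on an unknown component
    letter, a wrong digit count or non-numeric digits.
    """
    if not text:
        raise ICFCodeError("empty code")
    text = text.strip()
    if "-" in text:
        raise ICFCodeError(
            f"range notation {text!r} is a block, not a category code"
        )
    letter, digits = text[0], text[1:]
    try:
        component = Component(letter)
    except ValueError:
        raise ICFCodeError(f"unknown component letter {letter!r} in {text!r}") from None
    if not digits:
        raise ICFCodeError(f"code {text!r} has no digits")
    return ICFCode(component, digits)


def parent_code(code: ICFCode) -> Optional[ICFCode]:
    """The code one level up, or ``None`` for chapters.

    A second-level category's parent is its chapter (letter + first
    digit); deeper levels drop their last digit.
    """
    if code.level is Level.CHAPTER:
        return None
    if code.level is Level.SECOND:
        return code.chapter
    return ICFCode(code.component, code.digits[:-1])


@dataclass(frozen=True)
class CodeRange:
    """A block: a labeled inclusive range of codes sharing one chapter."""

    start: ICFCode
    end: ICFCode

    def __post_init__(self) -> None:
        if self.start.component is not self.end.component:
            raise ICFCodeError("block endpoints span components")
        if self.start.chapter != self.end.chapter:
            raise ICFCodeError("block endpoints span chapters")
        if self.start.digits > self.end.digits:
            raise ICFCodeError("block range is reversed")

    @property
    def component(self) -> Component:
        return self.start.component

    @property
    def chapter(self) -> ICFCode:
        return self.start.chapter

    def __contains__(self, code: ICFCode) -> bool:
        return (
            code.component is self.component
            and self.start.digits <= code.digits[: len(self.end.digits)]
            and code.digits[: len(self.start.digits)] <= self.end.digits
        )

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def parse_block(text: str) -> CodeRange:
    """Parse block notation such as ``"d330-d349"``."""
    parts = text.strip().split("-")
    if len(parts) != 2:
        raise ICFCodeError(f"malformed block notation {text!r}")
    return CodeRange(parse_code(parts[0]), parse_code(parts[1]))


@dataclass(eq=False)
class CategoryNode:
    """One node of the classification scheme: chapter, block or category."""

    code: Union[ICFCode, CodeRange]
    title: str
    kind: str  # "chapter" | "block" | "category"
    definition: Optional[str] = None
    parent: Optional["CategoryNode"] = None
    children: list = field(default_factory=list)

    @property
    def key(self) -> str:
        return str(self.code)

    @property
    def component(self) -> Component:
        return self.code.component

    def __repr__(self) -> str:  # keep node graphs readable in failures
        return f"CategoryNode({self.key}: {self.title!r})"


_KINDS = {"chapter", "block", "category"}


class CategoryRegistry:
    """An index of loaded :class:`CategoryNode` objects.

    Implements the mutually exclusive component classification: every
    node belongs to exactly one component, components b/s/d group under
    HealthDomain and e under ContextualFactor, and the two groups are
    disjoint by construction.
    """

    def __init__(self) -> None:
        self._index: dict[str, CategoryNode] = {}

    # -- construction -------------------------------------------------

    def _add(self, node: CategoryNode) -> None:
        if node.key in self._index:
            raise RegistryError(f"duplicate code {node.key}")
        self._index[node.key] = node

    # -- lookup -------------------------------------------------------

    def __contains__(self, code: Union[str, ICFCode]) -> bool:
        return str(code) in self._index

    def __len__(self) -> int:
        return len(self._index)

    def __iter__(self) -> Iterator[CategoryNode]:
        return iter(self._index.values())

    def get(self, code: Union[str, ICFCode]) -> CategoryNode:
        try:
            return self._index[str(code)]
        except KeyError:
            raise RegistryError(f"code {code} is not registered") from None

    def is_registered(self, code: Union[str, ICFCode]) -> bool:
        return str(code) in self._index

    def chapters(self, component: Component) -> list[CategoryNode]:
        return [
            n
            for n in self._index.values()
            if n.kind == "chapter" and n.component is component
        ]

    def categories(self, component: Optional[Component] = None) -> list[CategoryNode]:
        return [
            n
            for n in self._index.values()
            if n.kind != "block"
            and (component is None or n.component is component)
        ]


def load_registry(rows: Iterable[Mapping[str, str]]) -> CategoryRegistry:
    """Build a registry from ``code,title,kind,parent`` records.

    Parent references are resolved after all rows are read, so row order
    does not matter.  Raises :class:`RegistryError` on duplicate codes,
    orphan parent references or prefix violations.
    """
    registry = CategoryRegistry()
    parent_refs: list[tuple[CategoryNode, str]] = []
    for row in rows:
        kind = (row.get("kind") or "").strip()
        if kind not in _KINDS:
            raise RegistryError(f"unknown kind {kind!r} for row {dict(row)!r}")
        raw = (row.get("code") or "").strip()
        code: Union[ICFCode, CodeRange]
        if kind == "block":
            code = parse_block(raw)
        else:
            code = parse_code(raw)
            if kind == "chapter" and code.level is not Level.CHAPTER:
                raise RegistryError(f"chapter row {raw!r} is not a 1-digit code")
        node = CategoryNode(
            code=code,
            title=(row.get("title") or "").strip(),
            kind=kind,
            definition=(row.get("definition") or "").strip() or None,
        )
        registry._add(node)
        parent = (row.get("parent") or "").strip()
        if parent:
            parent_refs.append((node, parent))
        elif kind != "chapter":
            raise RegistryError(f"non-chapter node {node.key} lacks a parent")

    for node, parent_key in parent_refs:
        if parent_key not in registry:
            raise RegistryError(
                f"orphan parent reference {parent_key!r} from {node.key}"
            )
        parent = registry.get(parent_key)
        _check_attachment(node, parent)
        node.parent = parent
        parent.children.append(node)
    return registry


def _check_attachment(node: CategoryNode, parent: CategoryNode) -> None:
    """Enforce the prefix-extension invariant between child and parent."""
    if node.kind == "block":
        assert isinstance(node.code, CodeRange)
        if not (
            isinstance(parent.code, ICFCode)
            and parent.code == node.code.chapter
        ):
            raise RegistryError(
                f"block {node.key} must hang off its chapter, not {parent.key}"
            )
        return
    if isinstance(parent.code, CodeRange):
        raise RegistryError(
            f"category {node.key} may not have block {parent.key} as parent"
        )
    assert isinstance(node.code, ICFCode)
    if parent_code(node.code) != parent.code:
        raise RegistryError(
            f"prefix violation: parent of {node.key} must be "
            f"{parent_code(node.code)}, found {parent.key}"
        )


def load_registry_file(path) -> CategoryRegistry:
    """Load a registry from a TSV file (``code\\ttitle\\tkind\\tparent``).

    UTF-8; lines starting with ``#`` are comments; the first
    non-comment line is the header.
    """
    with open(path, encoding="utf-8") as fh:
        return _load_tsv_lines(fh)


def _load_tsv_lines(lines: Iterable[str]) -> CategoryRegistry:
    rows = []
    header: Optional[list[str]] = None
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [h.strip() for h in fields]
            continue
        rows.append(dict(zip(header, fields)))
    return load_registry(rows)


def default_registry() -> CategoryRegistry:
    """The registry shipped with the package.

    Covers the nine Activities & Participation chapters, the five
    Environmental Factors chapters, and every category used by the
    built-in case studies.  Deliberately partial: the full WHO catalogue
    of categories is out of scope.
    """
    ref = importlib.resources.files("icfkit").joinpath("data/icf_categories.tsv")
    with ref.open(encoding="utf-8") as fh:
        return _load_tsv_lines(fh)
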