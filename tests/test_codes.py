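"""Code syntax, hierarchy truncation and registry invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from icfkit import (
    Component,
    ICFCodeError,
    Level,
    RegistryError,
    default_registry,
    load_registry,
    parent_code,
    parse_block,
    parse_code,
)


@pytest.mark.parametrize(
    "text, letter, digits, level",
    [
        ("d410", "d", "410", Level.SECOND),
        ("e1151", "e", "1151", Level.THIRD),
        ("d4", "d", "4", Level.CHAPTER),
        ("b7300", "b", "7300", Level.THIRD),
        ("s73001", "s", "73001", Level.FOURTH),
    ],
)
def test_parse_code_examples(text, letter, digits, level):
    code = parse_code(text)
    assert code.component.letter == letter
    assert code.digits == digits
    assert code.level is level
    assert str(code) == text


@pytest.mark.parametrize(
    "bad", ["", "x123", "d", "d41", "d415370", "dxyz", "d330-d349", "e11a1"]
)
def test_parse_code_rejects_malformed(bad):
    with pytest.raises(ICFCodeError):
        parse_code(bad)


@pytest.mark.parametrize(
    "child, parent",
    [("d4153", "d415"), ("d410", "d4"), ("e1151", "e115"), ("s73001", "s7300")],
)
def test_parent_code_truncation(child, parent):
    assert parent_code(parse_code(child)) == parse_code(parent)


def test_chapters_are_roots():
    assert parent_code(parse_code("d4")) is None


@given(
    letter=st.sampled_from("bsde"),
    digits=st.text(alphabet="0123456789", min_size=1, max_size=5).filter(
        lambda d: len(d) in (1, 3, 4, 5)
    ),
)
def test_parse_render_identity(letter, digits):
    code = parse_code(letter + digits)
    assert parse_code(str(code)) == code
    # parent chains terminate at the chapter
    steps = 0
    while (code := parent_code(code)) is not None:
        steps += 1
    assert steps <= 3


def test_component_grouping_is_disjoint():
    health = {c for c in Component if c.group == "HealthDomain"}
    contextual = {c for c in Component if c.group == "ContextualFactor"}
    assert health | contextual == set(Component)
    assert not health & contextual
    assert Component.ENVIRONMENTAL_FACTORS in contextual


class TestRegistry:
    def test_default_registry_shape(self, registry):
        assert len(registry.chapters(Component.ACTIVITIES_AND_PARTICIPATION)) == 9
        assert len(registry.chapters(Component.ENVIRONMENTAL_FACTORS)) == 5
        for code in ("d410", "d4200", "d4153", "e1151", "e155", "e580", "d7202"):
            assert registry.is_registered(code)

    def test_parent_links_match_truncation(self, registry):
        from icfkit.codes import ICFCode

        for node in registry:
            if node.kind == "block" or node.parent is None:
                continue
            if isinstance(node.code, ICFCode):
                assert parent_code(node.code) == node.parent.code

    def test_block_is_range_not_code(self, registry):
        block = registry.get("d330-d349")
        assert block.kind == "block"
        assert parse_code("d345") in block.code
        assert parse_code("d350") not in block.code
        with pytest.raises(ICFCodeError):
            parse_code("d330-d349")

    def test_block_parse(self):
        rng = parse_block("d330-d349")
        assert rng.chapter == parse_code("d3")
        with pytest.raises(ICFCodeError):
            parse_block("d330-e349")

    @pytest.mark.parametrize(
        "rows, message",
        [
            (
                [
                    {"code": "d4", "title": "Mobility", "kind": "chapter", "parent": ""},
                    {"code": "d410", "title": "a", "kind": "category", "parent": "d4"},
                    {"code": "d410", "title": "b", "kind": "category", "parent": "d4"},
                ],
                "duplicate",
            ),
            (
                [{"code": "d910", "title": "a", "kind": "category", "parent": "d9"}],
                "orphan",
            ),
            (
                [
                    {"code": "d4", "title": "Mobility", "kind": "chapter", "parent": ""},
                    {"code": "d510", "title": "a", "kind": "category", "parent": "d4"},
                ],
                "prefix",
            ),
        ],
    )
    def test_load_registry_rejects_bad_rows(self, rows, message):
        with pytest.raises(RegistryError, match=message):
            load_registry(rows)

    def test_unknown_codes_are_parseable_but_unregistered(self, registry):
        code = parse_code("d999")
        assert not registry.is_registered(code)
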