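"""The Influence relation, coding conventions and defined classes."""

import pytest

from icfkit import (
    Component,
    FactorKind,
    InfluenceClass,
    Model,
    ModelError,
    Polarity,
    add_factor,
    add_influence,
    classify_influence,
    component_of,
    convention_of,
    influencing_factors,
    value,
)
from icfkit.casestudies import SyntheticSpec, generate_synthetic


@pytest.fixture()
def conrad_state():
    model = Model()
    conrad = model.add_human("Conrad", short_name="Conrad")
    hs = model.new_health_state(conrad, "state", short_name="Conrad_state_1")
    return model, hs


def test_environmental_factor_requires_e_code(conrad_state):
    model, _ = conrad_state
    with pytest.raises(ModelError, match="e-code"):
        add_factor(model, FactorKind.ENVIRONMENTAL, "no code")
    with pytest.raises(ModelError, match="environmental-factor"):
        add_factor(model, FactorKind.ENVIRONMENTAL, "wrong letter", code="d410")
    factor = add_factor(model, FactorKind.ENVIRONMENTAL, "building", code="e155")
    assert str(factor.code) == "e155"


def test_personal_factor_carries_no_code(conrad_state):
    model, hs = conrad_state
    with pytest.raises(ModelError, match="no ICF code"):
        add_factor(model, FactorKind.PERSONAL, "stubbornness", code="e155")
    pf = add_factor(model, FactorKind.PERSONAL, "stubbornness")
    inf = add_influence(model, hs, pf, Polarity.HINDRANCE, value("Hindrance", 1))
    assert inf.factor is pf  # personal factors are legal influencers


def test_add_influence_polarity_scale_agreement(conrad_state):
    model, hs = conrad_state
    factor = add_factor(model, FactorKind.ENVIRONMENTAL, "building", code="e155")
    inf = add_influence(model, hs, factor, Polarity.HINDRANCE, value("Hindrance", 3))
    assert inf.barrier_level.digit == 3 and inf.facilitation_level is None
    assert classify_influence(inf) is InfluenceClass.BARRIER
    with pytest.raises(ModelError, match="polarity mismatch"):
        add_influence(model, hs, factor, Polarity.FACILITATION, value("Hindrance", 3))
    with pytest.raises(ModelError, match="polarity mismatch"):
        add_influence(model, hs, factor, Polarity.HINDRANCE, value("Difficulty", 3))


def test_convention_dispatch(conrad_state):
    model, hs = conrad_state
    qa = model.add_qualified_activity(hs, "d410")
    comp = component_of(model, hs, Component.ACTIVITIES_AND_PARTICIPATION)
    factor = add_factor(model, FactorKind.ENVIRONMENTAL, "aid", code="e1151")
    by_target = {
        1: add_influence(model, hs, factor, Polarity.FACILITATION, value("Facilitation", 3)),
        2: add_influence(model, comp, factor, Polarity.FACILITATION, value("Facilitation", 2)),
        3: add_influence(model, qa, factor, Polarity.FACILITATION, value("Facilitation", 1)),
    }
    for convention, inf in by_target.items():
        assert convention_of(inf) == convention


def test_component_handle_is_shared(conrad_state):
    model, hs = conrad_state
    factor = add_factor(model, FactorKind.ENVIRONMENTAL, "aid", code="e1151")
    c1 = component_of(model, hs, Component.ACTIVITIES_AND_PARTICIPATION)
    add_influence(model, c1, factor, Polarity.FACILITATION, value("Facilitation", 1))
    c2 = component_of(model, hs, Component.ACTIVITIES_AND_PARTICIPATION)
    assert c1 is c2
    with pytest.raises(ModelError):
        component_of(model, hs, Component.ENVIRONMENTAL_FACTORS)


def test_influencing_factors_defined_class(conrad_state):
    model, hs = conrad_state
    used = add_factor(model, FactorKind.ENVIRONMENTAL, "aid", code="e1151")
    idle = add_factor(model, FactorKind.ENVIRONMENTAL, "unused", code="e580")
    add_influence(model, hs, used, Polarity.FACILITATION, value("Facilitation", 2))
    assert influencing_factors(model) == {used}
    assert idle not in influencing_factors(model)
    assert influencing_factors(Model()) == set()


@pytest.mark.parametrize("seed", [0, 9, 23])
def test_defined_classes_match_bruteforce(seed):
    model = generate_synthetic(
        SyntheticSpec(n_activities=20, n_influences=(4, 3, 3), seed=seed)
    )
    facilitators = {i for i in model.influences
                    if classify_influence(i) is InfluenceClass.FACILITATOR}
    barriers = {i for i in model.influences
                if classify_influence(i) is InfluenceClass.BARRIER}
    # oracle: the stored level slots decide polarity
    assert facilitators == {i for i in model.influences
                            if i.facilitation_level is not None}
    assert barriers == {i for i in model.influences
                        if i.barrier_level is not None}
    assert not facilitators & barriers
    assert facilitators | barriers == set(model.influences)
    # oracle for InfluencingFactor: exhaustive scan
    assert influencing_factors(model) == {i.factor for i in model.influences}


@pytest.mark.parametrize("seed", [2, 7])
def test_conventions_partition_influences(seed):
    model = generate_synthetic(
        SyntheticSpec(n_activities=10, n_influences=(3, 2, 4), seed=seed)
    )
    counts = {1: 0, 2: 0, 3: 0}
    for inf in model.influences:
        counts[convention_of(inf)] += 1
    assert sum(counts.values()) == len(model.influences)
    assert counts == {1: 3, 2: 2, 3: 4}
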