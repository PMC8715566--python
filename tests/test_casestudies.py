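"""Profile parsing/encoding, the worked fixtures, synthetic generation."""

import io

import pytest

from icfkit import (
    InfluenceClass,
    ProfileError,
    SyntheticSpec,
    classify_influence,
    convention_of,
    encode_profile,
    generate_synthetic,
    read_profile,
    to_triples,
    validate,
)
from icfkit.casestudies import profile_path


class TestReadProfile:
    def test_shipped_peter_profile(self):
        rows = read_profile(profile_path("peter"))
        assert [r.code for r in rows] == ["d410", "d4200", "d440", "d445"]
        assert [r.qualifier for r in rows] == [".1", ".2", ".4", ".3"]

    def test_shipped_conrad_profile_sections(self):
        rows = read_profile(profile_path("conrad"))
        assert len([r for r in rows if r.code.startswith("d")]) == 4
        assert len([r for r in rows if r.code.startswith("e")]) == 3
        assert rows[4].section == "facilitator"

    def test_malformed_row_reports_location(self):
        source = io.StringIO("code,qualifier\nq123,.1\n")
        with pytest.raises(ProfileError, match="row 1"):
            read_profile(source)

    def test_section_suffix_mismatch_rejected(self):
        source = io.StringIO("code,qualifier,section\ne155,.3,facilitator\n")
        with pytest.raises(ProfileError, match="facilitator section"):
            read_profile(source)


class TestEncodeProfile:
    def test_peter_rows_encode_to_four_activities(self):
        model = encode_profile(read_profile(profile_path("peter")), "Peter", "t1")
        qas = list(model.qualified_activities())
        assert len(qas) == 4
        digits = {qa.activity.key: qa.performance.digit for qa in qas}
        assert digits["d440"] == 4
        assert all(qa.capacity is None for qa in qas)
        assert validate(model).passed

    def test_conrad_convention_1_targets_state(self):
        model = encode_profile(
            read_profile(profile_path("conrad")), "Conrad", "t1", ef_convention=1
        )
        assert len(list(model.qualified_activities())) == 4
        assert len(model.influences) == 3
        assert {convention_of(i) for i in model.influences} == {1}
        kinds = [classify_influence(i) for i in model.influences]
        assert kinds.count(InfluenceClass.FACILITATOR) == 2
        assert kinds.count(InfluenceClass.BARRIER) == 1

    @pytest.mark.parametrize("convention, expected", [(2, 2), (3, 3)])
    def test_other_conventions(self, convention, expected):
        model = encode_profile(
            read_profile(profile_path("conrad")), "Conrad", "t1",
            ef_convention=convention,
        )
        assert {convention_of(i) for i in model.influences} == {expected}
        assert validate(model).passed

    def test_d_row_with_facilitation_suffix_rejected(self):
        with pytest.raises(ProfileError):
            read_profile(io.StringIO("code,qualifier\nd410,+3\n"))

    def test_unknown_convention_rejected(self):
        with pytest.raises(ProfileError, match="convention"):
            encode_profile([], "X", "t", ef_convention=4)

    def test_empty_rows_give_empty_valid_state(self):
        model = encode_profile([], "X", "t")
        assert len(model.health_states) == 1
        assert model.health_states[0].parts == []
        assert validate(model).passed

    def test_reencoding_is_deterministic(self):
        rows = read_profile(profile_path("conrad"))
        a = encode_profile(rows, "Conrad", "t1")
        b = encode_profile(rows, "Conrad", "t1")
        assert to_triples(a) == to_triples(b)


class TestFixtures:
    def test_paper_individual_names(self, all_fixtures):
        assert all_fixtures["e_case"].find("E_state_1_reacting_1")
        assert all_fixtures["peter"].find("Peter_state_1_changing_position_1")
        john_inf = all_fixtures["john"].find("John_state_2_lifting_1_ibuprofen_1")
        assert john_inf.level.label == "some"
        assert str(john_inf.factor.code) == "e1101"

    def test_e_case_single_unqualified_activity(self, all_fixtures):
        qas = list(all_fixtures["e_case"].qualified_activities())
        assert len(qas) == 1
        assert qas[0].activity.key == "d7202"
        assert qas[0].performance is None

    def test_all_fixtures_validate(self, all_fixtures):
        assert all(validate(m).passed for m in all_fixtures.values())

    def test_tabled_digits_roundtrip(self, all_fixtures):
        peter = {
            qa.activity.key: qa.performance.digit
            for qa in all_fixtures["peter"].qualified_activities()
        }
        assert peter == {"d410": 1, "d4200": 2, "d440": 4, "d445": 3}
        conrad = {
            qa.activity.key: qa.performance.digit
            for qa in all_fixtures["conrad"].qualified_activities()
        }
        assert conrad == {"d4153": 0, "d4154": 2, "d465": 3, "d850": 4}


class TestSynthetic:
    def test_zero_rate_forces_no_participations(self):
        model = generate_synthetic(
            SyntheticSpec(n_activities=10, participation_rate=0.0, seed=7)
        )
        assert model.participations() == []

    def test_same_seed_same_triples(self):
        spec = SyntheticSpec(n_activities=10, participation_rate=0.3, seed=7)
        assert to_triples(generate_synthetic(spec)) == to_triples(
            generate_synthetic(spec)
        )

    def test_requested_conventions_covered(self):
        model = generate_synthetic(
            SyntheticSpec(n_activities=5, n_influences=(1, 1, 1), seed=2)
        )
        assert {convention_of(i) for i in model.influences} == {1, 2, 3}

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_activities=-1)
        with pytest.raises(ValueError):
            SyntheticSpec(participation_rate=1.5)

    def test_unknown_fault_rejected(self):
        with pytest.raises(ValueError, match="unknown fault"):
            generate_synthetic(SyntheticSpec(faults=("no-such-rule",)))
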