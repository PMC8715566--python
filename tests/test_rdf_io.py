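"""Triple emission, OWL export faithfulness, Turtle round trips, SUMO."""

import io

import pytest
from rdflib import OWL, RDF, RDFS, Graph

from icfkit import (
    ICF,
    SUMO,
    Model,
    ModelError,
    SyntheticSpec,
    Triple,
    export_owl,
    fixtures,
    generate_synthetic,
    load_model,
    sumo_mappings,
    to_triples,
)
from icfkit.rdf_io import _OBJECT_PROPERTIES, lookup_mapping, ontology_counts, schema_graph


def _roundtrip(model):
    text = export_owl(model)
    return load_model(io.StringIO(text))


class TestToTriples:
    def test_peter_performance_triple(self, all_fixtures):
        triples = to_triples(all_fixtures["peter"])
        assert Triple(
            "Peter_state_1_changing_position_1", "performance", "MILD_difficulty"
        ) in triples
        assert Triple(
            "Peter_state_1_changing_position_1", "partOf", "Peter_state_1"
        ) in triples

    def test_e_case_partof(self, all_fixtures):
        triples = to_triples(all_fixtures["e_case"])
        assert Triple("E_state_1_reacting_1", "partOf", "E_state_1") in triples
        # no qualifier was recorded for the E. case
        assert not [t for t in triples if t.predicate in ("performance", "capacity")]

    def test_empty_state_emits_subject_link_only(self):
        model = Model()
        human = model.add_human("H", short_name="H")
        model.new_health_state(human, "empty", short_name="H_state_1")
        assert to_triples(model) == [Triple("H_state_1", "agent", "H")]

    def test_invalid_model_rejected(self):
        model = generate_synthetic(
            SyntheticSpec(n_activities=3, n_influences=(1, 0, 0), seed=2,
                          faults=("card.influence-polarity",))
        )
        with pytest.raises(ModelError, match="does not validate"):
            to_triples(model)

    def test_vocabulary_closed(self):
        model = generate_synthetic(
            SyntheticSpec(n_activities=15, n_influences=(2, 2, 2),
                          participation_rate=0.5, seed=6)
        )
        allowed = set(_OBJECT_PROPERTIES) | {"facilitates", "hinders", "influences"}
        assert {t.predicate for t in to_triples(model)} <= allowed


class TestExport:
    def test_serialization_is_deterministic(self):
        spec = SyntheticSpec(n_activities=12, n_influences=(2, 1, 2), seed=9)
        assert export_owl(generate_synthetic(spec)) == export_owl(
            generate_synthetic(spec)
        )

    def test_schema_only_export_for_empty_model(self):
        text = export_owl(Model())
        g = Graph().parse(io.StringIO(text), format="turtle")
        assert (ICF.Facilitator, RDF.type, OWL.Class) in g
        # no instance data beyond the enumerated individuals
        assert not list(g.subjects(RDF.type, ICF.HealthState))

    def test_facilitator_equivalent_class_unions_targets(self):
        g = schema_graph()
        definition = next(g.objects(ICF.Facilitator, OWL.equivalentClass))
        text = g.serialize(format="turtle")
        assert definition is not None
        for cls in ("HealthState", "InfluenceableComponent", "QualifiedActivity"):
            assert cls in text

    def test_functional_and_cardinality_axioms(self):
        g = schema_graph()
        for name, (_, _, functional, exact_one, _, _) in _OBJECT_PROPERTIES.items():
            if functional:
                assert (ICF[name], RDF.type, OWL.FunctionalProperty) in g, name
        # exact-1 slots carry a cardinality restriction on their domain
        restricted = {
            next(g.objects(r, OWL.onProperty))
            for r in g.subjects(RDF.type, OWL.Restriction)
            if next(g.objects(r, OWL.cardinality), None) is not None
        }
        assert {ICF.partOf, ICF.agent, ICF.activity, ICF.factor} <= restricted

    def test_disjointness_and_inverses_present(self):
        g = schema_graph()
        assert (ICF.EnvironmentalFactor, OWL.disjointWith, ICF.PersonalFactor) in g
        assert (ICF.ContextualFactor, OWL.disjointWith, ICF.HealthDomain) in g
        assert (ICF.facilitates, OWL.inverseOf, ICF.facilitatedBy) in g
        assert (ICF.hinders, OWL.inverseOf, ICF.hindrancedBy) in g
        assert (ICF.influences, OWL.inverseOf, ICF.influencedBy) in g

    def test_enumerated_scales_use_oneof(self):
        g = schema_graph()
        for name in ("Difficulty", "Hindrance", "Facilitation", "InfluencingManner"):
            assert next(g.objects(ICF[name], OWL.oneOf), None) is not None, name

    def test_counts_reported(self):
        g = Graph().parse(io.StringIO(export_owl(fixtures()["peter"])), format="turtle")
        counts = ontology_counts(g)
        assert counts["classes"] > 25
        assert counts["object_properties"] >= 17
        assert counts["individuals"] > 20


class TestRoundTrip:
    @pytest.mark.parametrize("name", ["e_case", "peter", "conrad", "john"])
    def test_fixture_roundtrip_isomorphic(self, name, all_fixtures):
        model = all_fixtures[name]
        assert set(to_triples(_roundtrip(model))) == set(to_triples(model))

    @pytest.mark.parametrize("seed", [0, 5, 17, 33])
    def test_synthetic_roundtrip_isomorphic(self, seed):
        model = generate_synthetic(
            SyntheticSpec(n_activities=10 + seed, n_influences=(2, 1, 2),
                          participation_rate=0.4, seed=seed)
        )
        assert set(to_triples(_roundtrip(model))) == set(to_triples(model))


class TestSumo:
    def test_stated_mappings(self):
        assert lookup_mapping("PersonalFactor").sumo == "BiologicalAttribute"
        assert lookup_mapping("EnvironmentalFactor").sumo == "Physical"
        assert lookup_mapping("partOf").sumo == "part"
        assert lookup_mapping("Difficulty").sumo == "SubjectiveAssessmentAttribute"
        assert lookup_mapping("ICFCategory").sumo == "Taxonomy"

    def test_each_local_entity_maps_at_most_once(self):
        locals_ = [e.local for e in sumo_mappings()]
        assert len(locals_) == len(set(locals_))

    def test_influencedby_target_unspecified(self):
        entry = lookup_mapping("influencedBy")
        assert entry.sumo is None and entry.note == "unspecified-target"

    def test_bridge_emitted_as_subclass_links(self):
        g = schema_graph()
        assert (ICF.Human, RDFS.subClassOf, SUMO.Human) in g
        assert (ICF.performance, RDFS.subPropertyOf, SUMO.manner) in g
        # SUMO is referenced, never imported: no SUMO-subject axioms
        assert not [s for s in g.subjects() if str(s).startswith(str(SUMO))]
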