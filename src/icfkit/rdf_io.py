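"""RDF triple emission, OWL (Turtle) export/import, and SUMO bridging.

The export carries the full formalization of the conceptual model:

* every class and object property, with ``rdfs:domain``/``rdfs:range``
  and an ``rdfs:comment`` definition;
* ``owl:FunctionalObjectProperty`` for every 0..1 multiplicity and an
  ``owl:ObjectExactCardinality`` restriction for every exact-1
  multiplicity;
* the qualifier scales and influencing manners as enumerated classes
  (``owl:oneOf``);
* disjointness axioms wherever sibling subclasses implement a mutually
  exclusive classification;
* equivalent-class definitions for the four defined classes
  (QualifiedParticipativeActivity, Facilitator, Barrier,
  InfluencingFactor) and the inverse properties facilitates / hinders /
  influences;
* the SUMO upper-ontology bridge as ``rdfs:subClassOf`` /
  ``rdfs:subPropertyOf`` links toward SUMO IRIs.  SUMO itself is never
  imported: referencing by IRI keeps exports desk-sized while staying
  mergeable with a full SUMO import.

Turtle is the canonical syntax.  IRIs live in a single base namespace
with fragments derived from entity short names (``Peter_state_1``
style), so identical models serialize identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from rdflib import OWL, RDF, RDFS, XSD, BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.compare import to_canonical_graph

from .codes import CategoryNode, Component, ICFCode, parse_code
from .healthstate import HealthState, LifeSituation, Model, ModelError, QualifiedActivity
from .influence import (
    ContextualFactor,
    FactorKind,
    Influence,
    InfluenceableComponent,
    InfluencingManner,
    Polarity,
    add_factor,
    add_influence,
    component_of,
)
from .qualifiers import DIFFICULTY, FACILITATION, HINDRANCE, QualifierValue
from .validation import validate

__all__ = [
    "ICF",
    "SUMO",
    "Triple",
    "MappingEntry",
    "to_triples",
    "export_owl",
    "load_model",
    "sumo_mappings",
    "ontology_counts",
]

ICF = Namespace("https://example.org/icfkit#")
SUMO = Namespace("http://www.ontologyportal.org/SUMO.owl#")


class Triple(NamedTuple):
    """A model triple over entity short names and relation names."""

    subject: str
    predicate: str
    object: str


@dataclass(frozen=True)
class MappingEntry:
    """One bridge link from a local entity to a SUMO entity."""

    local: str
    sumo: Optional[str]
    relation: str  # "subClassOf" | "subPropertyOf"
    note: Optional[str] = None


def sumo_mappings() -> list[MappingEntry]:
    """The SUMO bridge table.

    ``influencedBy`` is mapped with an unspecified target: the relation
    participates in the bridge but its SUMO counterpart is not named,
    so no property is guessed.
    """
    return [
        MappingEntry("ICFCategory", "Taxonomy", "subClassOf"),
        MappingEntry("Qualifier", "Attribute", "subClassOf"),
        MappingEntry("Difficulty", "SubjectiveAssessmentAttribute", "subClassOf"),
        MappingEntry("Human", "Human", "subClassOf"),
        MappingEntry("QualifiedActivity", "IntentionalProcess", "subClassOf"),
        MappingEntry("ActivityAndParticipation", "IntentionalProcess", "subClassOf"),
        MappingEntry("LifeSituation", "IntentionalProcess", "subClassOf"),
        MappingEntry("PersonalFactor", "BiologicalAttribute", "subClassOf"),
        MappingEntry("EnvironmentalFactor", "Physical", "subClassOf"),
        MappingEntry("ContextualFactor", "Entity", "subClassOf"),
        MappingEntry("performance", "manner", "subPropertyOf"),
        MappingEntry("capacity", "manner", "subPropertyOf"),
        MappingEntry("partOf", "part", "subPropertyOf"),
        MappingEntry("destination", "destination", "subPropertyOf"),
        MappingEntry("agent", "agent", "subPropertyOf"),
        MappingEntry(
            "influencedBy", None, "subPropertyOf", note="unspecified-target"
        ),
    ]


def lookup_mapping(local: str) -> Optional[MappingEntry]:
    for entry in sumo_mappings():
        if entry.local == local:
            return entry
    return None


# -- qualifier individual naming --------------------------------------


def qualifier_fragment(qv: QualifierValue) -> str:
    label = qv.label.upper().replace(" ", "_")
    return f"{label}_{qv.scale_name.lower()}"


_QUALIFIER_BY_FRAGMENT = {
    qualifier_fragment(v): v
    for sc in (DIFFICULTY, HINDRANCE, FACILITATION)
    for v in sc
}

_MANNER_BY_FRAGMENT = {f"{m.value}_manner": m for m in InfluencingManner}


def _category_fragment(code: ICFCode) -> str:
    return str(code).upper()  # d410 -> D410


# -- triple emission ---------------------------------------------------


def to_triples(model: Model) -> list[Triple]:
    """The complete, deterministic triple set of a validated model.

    Rejects models that do not pass validation: serializing an
    inconsistent model would bake its violations into the export.
    """
    report = validate(model)
    if not report.passed:
        raise ModelError(
            "model does not validate; fix these first:\n" + report.to_text()
        )
    triples: list[Triple] = []
    for hs in model.health_states:
        triples.append(Triple(hs.short_name, "agent", hs.subject.short_name))
        for qa in hs.parts:
            triples.append(Triple(qa.short_name, "partOf", hs.short_name))
            triples.append(Triple(qa.short_name, "activity", qa.activity_instance))
            if qa.performance is not None:
                triples.append(
                    Triple(qa.short_name, "performance", qualifier_fragment(qa.performance))
                )
            if qa.capacity is not None:
                triples.append(
                    Triple(qa.short_name, "capacity", qualifier_fragment(qa.capacity))
                )
            if qa.destination is not None:
                triples.append(
                    Triple(qa.short_name, "destination", qa.destination.short_name)
                )
    for inf in model.influences:
        relation = (
            "facilitatedBy"
            if inf.polarity is Polarity.FACILITATION
            else "hindrancedBy"
        )
        triples.append(Triple(inf.target.short_name, relation, inf.short_name))
        triples.append(Triple(inf.short_name, "factor", inf.factor.short_name))
        level_rel = (
            "facilitationLevel"
            if inf.polarity is Polarity.FACILITATION
            else "barrierLevel"
        )
        triples.append(
            Triple(inf.short_name, level_rel, qualifier_fragment(inf.level))
        )
        if inf.manner is not None:
            triples.append(
                Triple(inf.short_name, "influencingManner", f"{inf.manner.value}_manner")
            )
    return triples


# -- schema ------------------------------------------------------------

_CLASS_DEFINITIONS = {
    "ICF": "The classification framework: categories plus qualifiers.",
    "ICFCategory": "A classification unit: chapter, block or category.",
    "HealthDomain": "Categories describing health and well-being.",
    "BodyFunction": "Physiological functions of body systems.",
    "BodyStructure": "Anatomical parts of the body.",
    "ActivityAndParticipation": "Actions, tasks and areas of life.",
    "ContextualFactor": "External or personal modulators of functioning.",
    "EnvironmentalFactor": "Physically existing factors acting as barrier or facilitator.",
    "PersonalFactor": "Attributes of the person; not classified by the ICF.",
    "Qualifier": "A predefined value set measuring a quality of functioning.",
    "Difficulty": "Extent of difficulty in executing an action (performance/capacity).",
    "Hindrance": "Extent of a negative (barrier) influence.",
    "Facilitation": "Extent of a positive (facilitator) influence.",
    "Human": "A human being; the subject under assessment.",
    "HealthState": "A snapshot of the functioning of a human being.",
    "QualifiedActivity": "The reified assessment of one action within one health state.",
    "QualifiedParticipativeActivity": "A qualified activity directed at a life situation.",
    "LifeSituation": "A social setting an action is directed at.",
    "Influence": "The reified influence of a contextual factor on a health entity.",
    "Facilitator": "Influence that positively influences (facilitates) health states, influenceable components or activities.",
    "Barrier": "Influence that negatively influences (hinders) health states, influenceable components or activities.",
    "InfluencingFactor": "A contextual factor that exerts some influence.",
    "InfluencingManner": "How an influence originates (presence, absence, accessibility, ...).",
    "InfluenceableComponent": "One health-domain component of a health state (coding convention 2).",
    "InfluenceableHealthEntity": "Anything whose functioning contextual factors may influence.",
}

_SUBCLASS_AXIOMS = [
    ("HealthDomain", "ICFCategory"),
    ("ContextualFactor", "ICFCategory"),
    ("BodyFunction", "HealthDomain"),
    ("BodyStructure", "HealthDomain"),
    ("ActivityAndParticipation", "HealthDomain"),
    ("EnvironmentalFactor", "ContextualFactor"),
    ("PersonalFactor", "ContextualFactor"),
    ("Difficulty", "Qualifier"),
    ("Hindrance", "Qualifier"),
    ("Facilitation", "Qualifier"),
    ("Facilitator", "Influence"),
    ("Barrier", "Influence"),
    ("InfluencingFactor", "ContextualFactor"),
    ("QualifiedParticipativeActivity", "QualifiedActivity"),
    ("HealthState", "InfluenceableHealthEntity"),
    ("QualifiedActivity", "InfluenceableHealthEntity"),
    ("InfluenceableComponent", "InfluenceableHealthEntity"),
]

_DISJOINT_AXIOMS = [
    ("EnvironmentalFactor", "PersonalFactor"),
    ("ContextualFactor", "HealthDomain"),
    ("ActivityAndParticipation", "BodyFunction"),
    ("ActivityAndParticipation", "BodyStructure"),
    ("BodyFunction", "BodyStructure"),
]

#: name -> (domain, range, functional, exact_one, super_property, comment)
_OBJECT_PROPERTIES = {
    "manner": ("QualifiedActivity", "Difficulty", False, False, None,
               "Relates a process to a quality of its execution."),
    "performance": ("QualifiedActivity", "Difficulty", True, False, "manner",
                    "Difficulty executing the action in the current environment."),
    "capacity": ("QualifiedActivity", "Difficulty", True, False, "manner",
                 "Difficulty executing the action as a theoretical ability."),
    "destination": ("QualifiedActivity", "LifeSituation", True, False, None,
                    "The life situation an action is directed at."),
    "partOf": ("QualifiedActivity", "HealthState", True, True, None,
               "Aggregates an assessment into its single health state."),
    "agent": ("HealthState", "Human", True, True, None,
              "The subject whose functioning the health state describes."),
    "activity": ("QualifiedActivity", "ActivityAndParticipation", True, True, None,
                 "The category of the action being assessed."),
    "factor": ("Influence", "ContextualFactor", True, True, None,
               "The contextual factor that determines the influence."),
    "influencingManner": ("Influence", "InfluencingManner", True, False, None,
                          "How the factor's influence originates."),
    "facilitationLevel": ("Influence", "Facilitation", True, False, None,
                          "Extent of the positive influence."),
    "barrierLevel": ("Influence", "Hindrance", True, False, None,
                     "Extent of the negative influence."),
    "influencedBy": ("InfluenceableHealthEntity", "Influence", False, False, None,
                     "The influenced entity undergoes the influence."),
    "facilitatedBy": ("InfluenceableHealthEntity", "Influence", False, False,
                      "influencedBy", "Positive influence on the entity."),
    "hindrancedBy": ("InfluenceableHealthEntity", "Influence", False, False,
                     "influencedBy", "Negative influence on the entity."),
}

_INVERSES = [
    ("facilitates", "facilitatedBy"),
    ("hinders", "hindrancedBy"),
    ("influences", "influencedBy"),
]

_TARGET_UNION = ("HealthState", "InfluenceableComponent", "QualifiedActivity")


def _owl_list(g: Graph, items) -> BNode:
    head = BNode()
    Collection(g, head, list(items))
    return head


def _union(g: Graph, names) -> BNode:
    node = BNode()
    g.add((node, RDF.type, OWL.Class))
    g.add((node, OWL.unionOf, _owl_list(g, [ICF[n] for n in names])))
    return node


def _some(g: Graph, prop, cls) -> BNode:
    node = BNode()
    g.add((node, RDF.type, OWL.Restriction))
    g.add((node, OWL.onProperty, prop))
    g.add((node, OWL.someValuesFrom, cls))
    return node


def _intersection(g: Graph, members) -> BNode:
    node = BNode()
    g.add((node, RDF.type, OWL.Class))
    g.add((node, OWL.intersectionOf, _owl_list(g, members)))
    return node


def schema_graph(g: Optional[Graph] = None) -> Graph:
    """Build (or extend) a graph with the full ontology schema."""
    if g is None:
        g = Graph()
    g.bind("icf", ICF)
    g.bind("sumo", SUMO)
    g.bind("owl", OWL)
    ontology = URIRef(str(ICF).rstrip("#"))
    g.add((ontology, RDF.type, OWL.Ontology))

    for name, comment in _CLASS_DEFINITIONS.items():
        g.add((ICF[name], RDF.type, OWL.Class))
        g.add((ICF[name], RDFS.comment, Literal(comment)))
    for sub, sup in _SUBCLASS_AXIOMS:
        g.add((ICF[sub], RDFS.subClassOf, ICF[sup]))
    for a, b in _DISJOINT_AXIOMS:
        g.add((ICF[a], OWL.disjointWith, ICF[b]))

    # enumerated classes: qualifier scales and influencing manners
    for scale in (DIFFICULTY, HINDRANCE, FACILITATION):
        members = []
        for qv in scale:
            ind = ICF[qualifier_fragment(qv)]
            g.add((ind, RDF.type, OWL.NamedIndividual))
            g.add((ind, RDF.type, ICF[scale.name]))
            g.add((ind, RDFS.label, Literal(f"{qv.digit} {qv.label}")))
            g.add((ind, ICF.digit, Literal(qv.digit, datatype=XSD.integer)))
            members.append(ind)
        g.add((ICF[scale.name], OWL.oneOf, _owl_list(g, members)))
    manner_members = []
    for m in InfluencingManner:
        ind = ICF[f"{m.value}_manner"]
        g.add((ind, RDF.type, OWL.NamedIndividual))
        g.add((ind, RDF.type, ICF.InfluencingManner))
        g.add((ind, RDFS.label, Literal(m.value)))
        manner_members.append(ind)
    g.add((ICF.InfluencingManner, OWL.oneOf, _owl_list(g, manner_members)))

    # object properties
    for name, (dom, rng, functional, exact_one, sup, comment) in _OBJECT_PROPERTIES.items():
        p = ICF[name]
        g.add((p, RDF.type, OWL.ObjectProperty))
        g.add((p, RDFS.comment, Literal(comment)))
        if name in ("influencedBy", "facilitatedBy", "hindrancedBy"):
            g.add((p, RDFS.domain, _union(g, _TARGET_UNION)))
        else:
            g.add((p, RDFS.domain, ICF[dom]))
        g.add((p, RDFS.range, ICF[rng]))
        if functional:
            g.add((p, RDF.type, OWL.FunctionalProperty))
        if sup:
            g.add((p, RDFS.subPropertyOf, ICF[sup]))
        if exact_one:
            restriction = BNode()
            g.add((restriction, RDF.type, OWL.Restriction))
            g.add((restriction, OWL.onProperty, p))
            g.add((restriction, OWL.cardinality, Literal(1, datatype=XSD.nonNegativeInteger)))
            g.add((ICF[dom], RDFS.subClassOf, restriction))
    for inv, base in _INVERSES:
        g.add((ICF[inv], RDF.type, OWL.ObjectProperty))
        g.add((ICF[inv], OWL.inverseOf, ICF[base]))
        g.add((ICF[inv], RDFS.domain, ICF.Influence))
        g.add((ICF[inv], RDFS.range, _union(g, _TARGET_UNION)))

    # defined classes (equivalent-class axioms)
    g.add((
        ICF.QualifiedParticipativeActivity,
        OWL.equivalentClass,
        _intersection(
            g,
            [ICF.QualifiedActivity, _some(g, ICF.destination, ICF.LifeSituation)],
        ),
    ))
    g.add((
        ICF.Facilitator,
        OWL.equivalentClass,
        _intersection(
            g, [ICF.Influence, _some(g, ICF.facilitates, _union(g, _TARGET_UNION))]
        ),
    ))
    g.add((
        ICF.Barrier,
        OWL.equivalentClass,
        _intersection(
            g, [ICF.Influence, _some(g, ICF.hinders, _union(g, _TARGET_UNION))]
        ),
    ))
    inv_factor = BNode()
    g.add((inv_factor, OWL.inverseOf, ICF.factor))
    g.add((
        ICF.InfluencingFactor,
        OWL.equivalentClass,
        _intersection(
            g, [ICF.ContextualFactor, _some(g, inv_factor, ICF.Influence)]
        ),
    ))

    # SUMO bridge
    for entry in sumo_mappings():
        if entry.sumo is None:
            g.add((
                ICF[entry.local],
                RDFS.comment,
                Literal(f"SUMO mapping: {entry.note or 'unspecified'}"),
            ))
            continue
        predicate = (
            RDFS.subClassOf if entry.relation == "subClassOf" else RDFS.subPropertyOf
        )
        g.add((ICF[entry.local], predicate, SUMO[entry.sumo]))
    return g


def serialize_canonical(g: Graph) -> str:
    """Turtle with structure-derived blank-node labels: identical graphs
    serialize byte-identically, independent of construction order."""
    canonical = Graph()
    for triple in to_canonical_graph(g):
        canonical.add(triple)
    canonical.bind("icf", ICF)
    canonical.bind("sumo", SUMO)
    canonical.bind("owl", OWL)
    return canonical.serialize(format="turtle")


def _category_class(g: Graph, node: CategoryNode, registry) -> URIRef:
    """Emit the owl:Class chain for a category code (leaf to chapter)."""
    assert isinstance(node.code, ICFCode)
    cls = ICF[_category_fragment(node.code)]
    if (cls, RDF.type, OWL.Class) in g:
        return cls
    g.add((cls, RDF.type, OWL.Class))
    g.add((cls, RDFS.label, Literal(node.title)))
    g.add((cls, ICF.code, Literal(str(node.code))))
    parent = node.parent
    if parent is not None and isinstance(parent.code, ICFCode):
        g.add((cls, RDFS.subClassOf, _category_class(g, parent, registry)))
    else:
        g.add((cls, RDFS.subClassOf, ICF[node.component.class_name]))
    return cls


def export_owl(model: Model, target=None) -> str:
    """Serialize a model (schema + individuals) as Turtle.

    ``target`` may be a path or a writable text/binary stream; the
    Turtle text is returned either way.  An empty model yields the
    schema axioms only.  The model must validate.
    """
    report = validate(model)
    if not report.passed:
        raise ModelError(
            "model does not validate; fix these first:\n" + report.to_text()
        )
    g = schema_graph()

    for human in model.humans:
        iri = ICF[human.short_name]
        g.add((iri, RDF.type, ICF.Human))
        g.add((iri, RDFS.label, Literal(human.name)))
    for ls in model.life_situations:
        iri = ICF[ls.short_name]
        g.add((iri, RDF.type, ICF.LifeSituation))
        g.add((iri, RDFS.label, Literal(ls.label)))
    for hs in model.health_states:
        iri = ICF[hs.short_name]
        g.add((iri, RDF.type, ICF.HealthState))
        g.add((iri, RDFS.label, Literal(hs.label)))
        g.add((iri, ICF.agent, ICF[hs.subject.short_name]))
        for qa in hs.parts:
            _export_qa(g, model, qa, iri)
    for factor in model.factors:
        iri = ICF[factor.short_name]
        g.add((iri, RDFS.label, Literal(factor.label)))
        if factor.kind is FactorKind.ENVIRONMENTAL:
            node = model.resolve_category(factor.code) if model.registry.is_registered(
                factor.code
            ) else CategoryNode(factor.code, str(factor.code), "category")
            g.add((iri, RDF.type, _category_class(g, node, model.registry)))
        else:
            g.add((iri, RDF.type, ICF.PersonalFactor))
    for inf in model.influences:
        _export_influence(g, inf)

    text = serialize_canonical(g)
    if target is not None:
        if hasattr(target, "write"):
            try:
                target.write(text)
            except TypeError:
                target.write(text.encode("utf-8"))
        else:
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def _export_qa(g: Graph, model: Model, qa: QualifiedActivity, hs_iri: URIRef) -> None:
    iri = ICF[qa.short_name]
    g.add((iri, RDF.type, ICF.QualifiedActivity))
    g.add((iri, ICF.partOf, hs_iri))
    act = ICF[qa.activity_instance]
    g.add((act, RDF.type, _category_class(g, qa.activity, model.registry)))
    g.add((act, RDFS.label, Literal(qa.activity.title)))
    g.add((iri, ICF.activity, act))
    if qa.performance is not None:
        g.add((iri, ICF.performance, ICF[qualifier_fragment(qa.performance)]))
    if qa.capacity is not None:
        g.add((iri, ICF.capacity, ICF[qualifier_fragment(qa.capacity)]))
    if qa.destination is not None:
        g.add((iri, ICF.destination, ICF[qa.destination.short_name]))


def _export_influence(g: Graph, inf: Influence) -> None:
    iri = ICF[inf.short_name]
    g.add((iri, RDF.type, ICF.Influence))
    target_iri = ICF[inf.target.short_name]
    if isinstance(inf.target, InfluenceableComponent):
        g.add((target_iri, RDF.type, ICF.InfluenceableComponent))
        g.add((target_iri, ICF.partOf, ICF[inf.target.health_state.short_name]))
    if inf.polarity is Polarity.FACILITATION:
        g.add((target_iri, ICF.facilitatedBy, iri))
        g.add((iri, ICF.facilitationLevel, ICF[qualifier_fragment(inf.level)]))
    else:
        g.add((target_iri, ICF.hindrancedBy, iri))
        g.add((iri, ICF.barrierLevel, ICF[qualifier_fragment(inf.level)]))
    g.add((iri, ICF.factor, ICF[inf.factor.short_name]))
    if inf.manner is not None:
        g.add((iri, ICF.influencingManner, ICF[f"{inf.manner.value}_manner"]))


# -- import ------------------------------------------------------------


def _fragment(iri: URIRef) -> str:
    return str(iri).rsplit("#", 1)[-1]


def load_model(source, registry=None) -> Model:
    """Re-import a Turtle export into a fresh :class:`Model`.

    Restricted to this ontology's vocabulary: unknown classes and
    properties are ignored.  Entities are reconstructed in sorted
    short-name order, so imports are deterministic regardless of triple
    order in the file.
    """
    g = Graph()
    if hasattr(source, "read"):
        g.parse(source, format="turtle")
    else:
        g.parse(str(source), format="turtle")

    model = Model(registry=registry)

    def label_of(iri, default=""):
        for _, _, lbl in g.triples((iri, RDFS.label, None)):
            return str(lbl)
        return default

    humans = {}
    for iri in sorted(g.subjects(RDF.type, ICF.Human)):
        if not isinstance(iri, URIRef) or _fragment(iri) == "Human":
            continue
        frag = _fragment(iri)
        humans[iri] = model.add_human(label_of(iri, frag), short_name=frag)

    situations = {}
    for iri in sorted(g.subjects(RDF.type, ICF.LifeSituation)):
        if not isinstance(iri, URIRef):
            continue
        frag = _fragment(iri)
        situations[iri] = model.add_life_situation(label_of(iri, frag), short_name=frag)

    # category individuals: instance -> CategoryNode resolved via icf:code
    def category_node_of(instance_iri) -> Optional[CategoryNode]:
        for cls in g.objects(instance_iri, RDF.type):
            for code_lit in g.objects(cls, ICF.code):
                return model.resolve_category(parse_code(str(code_lit)))
        return None

    states = {}
    for iri in sorted(g.subjects(RDF.type, ICF.HealthState)):
        if not isinstance(iri, URIRef):
            continue
        subject_iri = next(g.objects(iri, ICF.agent), None)
        if subject_iri is None or subject_iri not in humans:
            raise ModelError(f"health state {iri} lacks a subject link")
        frag = _fragment(iri)
        states[iri] = model.new_health_state(
            humans[subject_iri], label_of(iri, frag), short_name=frag
        )

    qas = {}
    for iri in sorted(g.subjects(RDF.type, ICF.QualifiedActivity)):
        if not isinstance(iri, URIRef) or _fragment(iri) == "QualifiedActivity":
            continue
        hs_iri = next(g.objects(iri, ICF.partOf), None)
        if hs_iri not in states:
            raise ModelError(f"qualified activity {iri} lacks a partOf link")
        act_iri = next(g.objects(iri, ICF.activity), None)
        node = category_node_of(act_iri) if act_iri is not None else None
        if node is None:
            raise ModelError(f"qualified activity {iri} lacks an activity link")

        def qval(prop):
            obj = next(g.objects(iri, prop), None)
            return _QUALIFIER_BY_FRAGMENT[_fragment(obj)] if obj is not None else None

        qa = model.add_qualified_activity(
            states[hs_iri],
            node,
            performance=qval(ICF.performance),
            capacity=qval(ICF.capacity),
            short_name=_fragment(iri),
            activity_instance=_fragment(act_iri),
        )
        dest = next(g.objects(iri, ICF.destination), None)
        if dest is not None:
            qa.destination = situations[dest]
        qas[iri] = qa

    factors = {}
    factor_iris = set()
    for iri in g.subjects(RDF.type, None):
        if not isinstance(iri, URIRef):
            continue
        for cls in g.objects(iri, RDF.type):
            if cls == ICF.PersonalFactor and _fragment(iri) != "PersonalFactor":
                factor_iris.add((iri, None))
            elif isinstance(cls, URIRef):
                for code_lit in g.objects(cls, ICF.code):
                    code = parse_code(str(code_lit))
                    if code.component is Component.ENVIRONMENTAL_FACTORS:
                        factor_iris.add((iri, code))
    for iri, code in sorted(factor_iris, key=lambda t: str(t[0])):
        frag = _fragment(iri)
        if code is None:
            factors[iri] = add_factor(
                model, FactorKind.PERSONAL, label_of(iri, frag), short_name=frag
            )
        else:
            factors[iri] = add_factor(
                model,
                FactorKind.ENVIRONMENTAL,
                label_of(iri, frag),
                code=code,
                short_name=frag,
            )

    # influence targets may be convention-2 component handles
    components = {}
    for iri in sorted(g.subjects(RDF.type, ICF.InfluenceableComponent)):
        if not isinstance(iri, URIRef):
            continue
        hs_iri = next(g.objects(iri, ICF.partOf), None)
        if hs_iri not in states:
            raise ModelError(f"influenceable component {iri} lacks its state")
        frag = _fragment(iri)
        suffix = frag[len(states[hs_iri].short_name) + 1 :].lower()
        comp = next(
            (c for c in Component if c.class_name.lower() == suffix), None
        )
        if comp is None:
            raise ModelError(f"cannot recover component kind from {frag!r}")
        components[iri] = component_of(model, states[hs_iri], comp)

    for iri in sorted(g.subjects(RDF.type, ICF.Influence)):
        if not isinstance(iri, URIRef) or _fragment(iri) == "Influence":
            continue
        factor_iri = next(g.objects(iri, ICF.factor), None)
        target_iri = next(g.subjects(ICF.facilitatedBy, iri), None)
        polarity = Polarity.FACILITATION
        level_prop = ICF.facilitationLevel
        if target_iri is None:
            target_iri = next(g.subjects(ICF.hindrancedBy, iri), None)
            polarity = Polarity.HINDRANCE
            level_prop = ICF.barrierLevel
        level_iri = next(g.objects(iri, level_prop), None)
        if factor_iri not in factors or target_iri is None or level_iri is None:
            raise ModelError(f"influence {iri} is incomplete")
        target = (
            states.get(target_iri)
            or components.get(target_iri)
            or qas.get(target_iri)
        )
        if target is None:
            raise ModelError(f"influence {iri} has an unknown target {target_iri}")
        manner_iri = next(g.objects(iri, ICF.influencingManner), None)
        add_influence(
            model,
            target,
            factors[factor_iri],
            polarity,
            _QUALIFIER_BY_FRAGMENT[_fragment(level_iri)],
            manner=_MANNER_BY_FRAGMENT[_fragment(manner_iri)]
            if manner_iri is not None
            else None,
            short_name=_fragment(iri),
        )
    return model


def ontology_counts(g: Graph) -> dict:
    """Counts of named classes, object properties and individuals.

    The implementation reports its own inventory; the counts depend on
    how many category classes a model touches.
    """
    classes = {s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}
    props = {
        s for s in g.subjects(RDF.type, OWL.ObjectProperty) if isinstance(s, URIRef)
    }
    class_like = classes | {OWL.Class, OWL.ObjectProperty, OWL.Ontology,
                            OWL.Restriction, OWL.NamedIndividual, OWL.FunctionalProperty}
    individuals = set()
    for s, _, o in g.triples((None, RDF.type, None)):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            if o in classes and s not in classes and s not in props:
                individuals.add(s)
    return {
        "classes": len(classes),
        "object_properties": len(props),
        "individuals": len(individuals),
    }
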