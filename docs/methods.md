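# Methods

## Scope and model

icfkit formalizes the two most distinctive ICF components — Activities &
Participation (d) and Environmental Factors (e) — as an executable domain
model with OWL serialization. Body Functions and Body Structures are
reserved extension points only: the `HealthState` aggregate is designed
to also hold qualified body functions/structures one day, and the
convention-2 `InfluenceableComponent` handle already names all three
health-domain components, but no b/s qualifier scales or assessments are
implemented. Personal factors are represented as a concept (a disjoint
`ContextualFactor` kind that may drive an `Influence`) without any
internal classification, mirroring their status in the ICF itself.

The two load-bearing design patterns:

* **Reified n-ary relations.** An assessment is not a property value but
  an individual. `QualifiedActivity` ties together (health state,
  d-category, performance, capacity, optional destination);
  `Influence` ties together (factor, target, polarity, level, optional
  manner). This is the standard "introduce a class for the relation"
  pattern; it is what lets a level or a manner be *about* the
  relationship rather than about either endpoint.
* **Defined vs. primitive classes.** Four classes are inferred, never
  asserted: `QualifiedParticipativeActivity` (has a destination),
  `Facilitator` / `Barrier` (polarity of the influence link), and
  `InfluencingFactor` (appears as the factor of ≥1 influence). The
  Python API computes membership by rule; the OWL export carries the
  equivalent-class axioms so an external reasoner reaches the same
  classification.

The agent of an activity is reached indirectly
(`QualifiedActivity —partOf→ HealthState —agent→ Human`); there is no
direct activity→agent link, which keeps one assessment anchored to
exactly one snapshot of one person.

## Qualifier scales

Scales are closed enumerations of value individuals (not literals, so
values can be subjects of further statements; not extendable at run
time, matching `owl:oneOf` semantics). Digits follow the ICF generic
convention: 0–4 grade the extent, 8 marks an unspecified extent.

| scale | digits → labels |
|---|---|
| Difficulty | 0 no problem, 1 mild, 2 moderate, 3 severe, 4 complete, 8 not specified |
| Hindrance | 0 no, 1 mild, 2 moderate, 3 severe, 4 complete, 8 some |
| Facilitation | 0 no, 1 mild, 2 moderate, 3 substantial, 4 complete, 8 some |

Open design point, decided here: the influence scales clearly carry a
sixth "some" member, while printed difficulty examples only use 0–4. We
give Difficulty a symmetric sixth member (8, "not specified") because
the ICF generic scale reserves digit 8 for exactly that; nothing in the
toolkit forces its use. Percentage ranges default to the ICF generic
bands (0–4, 5–24, 25–49, 50–95, 96–100 %) and are overridable per scale
via a YAML file (localization); digits 0–4 must then still partition
[0, 100].

Suffix syntax: `.d` is difficulty on d-codes and hindrance (barrier) on
e-codes; `+d` is facilitation and legal only on e-codes. This is the
standard ICF annotation dialect.

## Codes and the registry

Code syntax is strict: component letter b/s/d/e plus 1 (chapter), 3
(second), 4 (third) or 5 (fourth-level) digits. The parent of a deeper
code is its digit-truncation; a second-level code's parent is its
chapter. Blocks (`d330-d349`) are labeled code *ranges*, not codable
units: `parse_code` rejects range syntax and the registry stores blocks
as range nodes attached to their chapter, outside the prefix hierarchy
used for parent/child checks — a representation choice, since blocks
are structural groupings only.

The shipped registry is deliberately partial (the full WHO catalogue is
a non-goal): the nine A&P chapters, the five EF chapters, one example
block and the ~20 categories the worked case studies touch. Every
operation works on any registry subset; unknown codes are parseable and
usable but flagged by validation as warnings, not errors.

## Validation

Twelve native rules cover what the exported OWL axioms express:
disjointness (sibling classes implementing mutually exclusive
classifications: environmental/personal, contextual factor/health
domain, the three health-domain components), cardinality (one health
state per qualified activity, one subject per state, exactly one
factor/target/polarity per influence) and domain/range (Difficulty
values only on performance/capacity, polarity-matched level scales,
d-categories only as activities, e-codes only on environmental
factors). Reports are produced all-at-once, sorted by (rule, entity,
message) for determinism, and rendered as text or JSON. Full OWL-DL
reasoning is out of scope by design; the Turtle export exists precisely
so a desktop reasoner can do that part.

Every rule has a dedicated fault injector in the synthetic generator
that provably triggers that rule and nothing else — the completeness
property the test suite and the acceptance script both measure.

## Serialization

Turtle is canonical. The export always contains the full schema
(classes with `rdfs:comment` definitions, object properties with
domain/range, `owl:FunctionalObjectProperty` for every 0..1 slot, an
exact-cardinality-1 restriction for every mandatory slot, `owl:oneOf`
enumerations, disjointness, the four equivalent-class definitions, the
facilitates/hinders/influences inverses with the three-way
`owl:unionOf` range) plus the model's individuals. Data triples assert
`target —facilitatedBy/hindrancedBy→ influence`; the inverse direction
is derivable from the schema axioms rather than materialized. The SUMO
bridge (16 entries, e.g. `EnvironmentalFactor ⊑ sumo:Physical`,
`partOf ⊑ sumo:part`) is emitted as subclass/subproperty links to SUMO
IRIs without importing SUMO; the one relation whose upper-ontology
target is not fixed (`influencedBy`) carries an explicit
"unspecified-target" marker instead of a guess.

Determinism: IRI fragments are entity short names
(`Peter_state_1_changing_position_1` style, auto-generated by slugging
with per-state counters, overridable), and blank nodes are relabeled by
graph-structure canonicalization before serialization, so identical
models export byte-identically across processes. Import is restricted
to this vocabulary; convention-2 component handles are reconstructed
from their `partOf` link plus the component suffix of their generated
short name, so hand-renamed handles are the one thing a round trip does
not guarantee.

## Synthetic generator

`generate_synthetic(SyntheticSpec(...))` emulates a single-subject
categorical assessment: `n_activities` qualified activities drawn
uniformly from the registry's d-categories with difficulty digits 0–4
(capacity present half the time), a `participation_rate` share given
destination life situations, and `n_influences = (c1, c2, c3)`
influences per coding convention with 80 % environmental / 20 %
personal factors, uniform polarity, levels from {0,1,2,3,4,8} and a
manner half the time. Defaults (10 activities, (2,1,1) influences,
participation 0.3) match the shape of the validation scenarios:
activities alone, participation, activities with environmental factors.
All draws come from one `random.Random(seed)`, so a spec is a complete
recipe.

What the generator does *not* emulate — and therefore what passing
property suites do not show about real data: clinically plausible
co-occurrence of categories, longitudinal multi-state histories,
narrative vignettes needing human coding, and b/s-component
assessments. The oracles it supports (defined-class inference vs.
exhaustive filtering, export/import isomorphism, one-fault-per-rule)
are logical properties of the model, not epidemiological ones.

## Problem sizes

The property suites run on 100 seeded models of 3–40 activities and up
to 8 influences each (a few hundred entities per model at most), which
exercises every convention, polarity and qualifier digit many times
over; inference oracles are O(n) scans, so larger models add runtime
without adding coverage.

## Known limitations

* No reasoner-backed consistency check; the native rules are the
  enforced subset.
* The registry ships titles only, no textual definitions.
* Whether a qualified activity may reference a chapter rather than a
  leaf category is not restricted (worked examples only use
  second/third-level categories); validation accepts any d-code.
* Cross-state influences (an influence whose target lives in another
  subject's state) are representable and currently not flagged; all
  worked examples stay within one state.
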