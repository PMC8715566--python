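# icfkit

An executable knowledge-representation toolkit for the **Activities &
Participation** (d) and **Environmental Factors** (e) components of WHO's
International Classification of Functioning, Disability and Health (ICF).

The ICF describes a person's functioning as coded assessments: category
codes (`d410` *Changing basic body positions*, `e1151` *Assistive products
for personal mobility*, …) paired with qualifier digits that grade
difficulty, or the extent to which an environmental factor acts as a
facilitator (`+3`) or barrier (`.3`). icfkit turns that coding scheme into
a typed, checkable, OWL-serializable domain model for coders,
classification researchers and terminology engineers.

## The model

Two reified n-ary relations carry the semantics (the W3C "introduce a
class for the relation" pattern):

* **QualifiedActivity** links one health state, one d-category and up to
  two Difficulty values via the sub-relations of *manner*:

  `QualifiedActivity —activity→ d-category, —performance→ Difficulty,
  —capacity→ Difficulty, —destination→ LifeSituation (0..1),
  —partOf→ HealthState (exactly 1)`

  Participation is *instance-level* and inferred, never asserted:

  `QualifiedParticipativeActivity ≡ QualifiedActivity ⊓ ∃destination.LifeSituation`

* **Influence** links one contextual factor to one influenced entity with
  a polarity-matched level and an optional origin (*presence*, *absence*,
  *accessibility*, …):

  `Influence —factor→ ContextualFactor, —facilitationLevel→ Facilitation
  XOR —barrierLevel→ Hindrance; target —facilitatedBy|hindrancedBy→ Influence`

  `Facilitator ≡ Influence ⊓ ∃facilitates.(HealthState ⊔
  InfluenceableComponent ⊔ QualifiedActivity)` (Barrier analogously), and
  the three ICF coding conventions for environmental factors are exactly
  the three target types: the whole health state (1), one component of it
  (2), or a single qualified activity (3).

Qualifier scales are closed enumerations of individuals (digits 0–4 plus
8 "some/not specified"); the category registry is a deliberately partial,
loadable subset of the classification tree; models validate against the
disjointness, cardinality and domain/range axioms that the Turtle export
carries as OWL constructs; and every class/property is bridged to the
SUMO upper ontology by `rdfs:subClassOf`/`rdfs:subPropertyOf` links
(SUMO is referenced by IRI, never imported).

## Worked example

Encode a shipped categorical profile (the Conrad case: four mobility
activities plus three environmental factors coded with convention 1)
and query it back:

```sh
icfkit encode $(python -c "import icfkit; print(icfkit.profile_path('conrad'))") \
       --subject Conrad --label 2021_review -o conrad.ttl
icfkit query conrad.ttl facilitators
icfkit query conrad.ttl barriers
```

prints

```
e1151	Conrad_state_1_assistive_products_and_technology_for_personal_mobility_1
e580	Conrad_state_1_health_services_systems_and_policies_1
```

and

```
e155	Conrad_state_1_design_construction_and_building_products_and_technology_of_buildings_for_private_use_1
```

i.e. the assistive-mobility products (+3 substantial) and the health
services (+2 moderate) are inferred members of the defined class
Facilitator, while the building design (.3 severe) is a Barrier.
`icfkit validate conrad.ttl` exits 0 with `validation passed: no
violations`, and the same workflows are available in Python:

```python
import icfkit as k

john = k.fixtures()["john"]          # severe lifting difficulty, eased by ibuprofen
inf, = john.influences
k.convention_of(inf)                  # 3  (influence on the activity itself)
k.classify_influence(inf)             # InfluenceClass.FACILITATOR
inf.level.label                       # 'some'
print(k.export_owl(john))             # deterministic Turtle, schema + individuals
```

`icfkit synth --seed 7 -o model.ttl` generates a reproducible synthetic
assessment, optionally with injected consistency faults
(`--fault card.influence-polarity`) for testing validators downstream.

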