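# Methods

## Problem and scope

Botanical descriptions in Spanish floras use a telegraphic sublanguage:
clauses terminated by `.` `:` `;` each describe one structure; comma-bounded
chunks carry states, measurements and short prepositional phrases. morphex
structures this sublanguage with deterministic rules. It does not attempt
general Spanish parsing: relative clauses and most prepositional phrases are
delimited (`verb_string`, `constraint_preposition`) rather than analysed,
with entity tokens inside them still extracted so later association can see
them.

## Segmentation

A period splits a clause only when followed by whitespace plus a token that
is neither numeric nor an opening parenthesis, or at end of text; this keeps
decimals ("3.3") and unit abbreviations ("cm.,") intact, which real clauses
contain mid-stream. Commas inside parentheses never split chunks, so
parenthetical asides ("(rara vez opuestas)") stay attached. Text is NFC-
normalised once; accents are preserved throughout.

## Tagging and the knowledge base

Closed-class Spanish function words, units and verbs ship in a lexicon
(~400 entries, TSV, user-replaceable); open-class botanical nouns (E) and
states (A) are seeded with ~70 nouns and ~300 inflected state forms.
Numbers, ranges and "×" are recognised structurally and always tagged Z/G.
Unknown tokens are X until the bootstrapping loop resolves them: rules
propagate the state role across tokens chained by the preposition *a* and —
as an extension — across coordinations (*o/u/y/e*). The loop re-tags the
corpus each cycle and stops at a fixpoint or after `max_iterations` (default
10; fixture corpora converge in ≤ 3). The knowledge base only grows, records
the rule and iteration behind each entry, and round-trips through TSV so
learned roles are inspectable.

Gender and number come from suffix heuristics (-a/-as feminine, -o/-os
masculine, -e/-es unmarked) with an explicit exception list for nouns whose
ending belies their gender (*base*, *ápice*, *margen*, *envés*, *tricomas*,
*estigma*, ...). Unmarked values are treated as agreeing with anything, so
gender-invariant adjectives ("verde", "pubescente") never block
association.

## Dependency trees

The annotation rules are stated over minimal head/child/sibling shapes: the
chunk head is the leftmost E, else A, else Z; states and numerals hang off
the head; an adverb attaches to the nearest following content token (else
nearest preceding); parentheticals attach to the token before the
parenthesis; prepositions and verbs open subtrees; in coordinations the
conjunction hangs under the first conjunct. Any parser backend meeting these
attachment contracts can be substituted; the bundled heuristic one is
deterministic and total on tagged chunks. Measurement expressions are parsed
from the token sequence directly, since their internal tree shape carries no
extra information.

## Semantic rules

- **Entities**: one structure per maximal related-E group; an immediately
  following second noun becomes the `modifier` ("frutos nueces").
- **States**: each state is translated and resolved against the
  character-name index; when several character names share the state
  ("elliptic" → arrangement, shape) one character per name is emitted,
  alphabetically, each with the verbatim note `Carácter repetido`; unknown
  states get the placeholder name `unknown_character` and a note, never a
  crash. Adjacent states with the same character-name set merge into one
  value ("verde amarillento pálido a verdosas", one colouration character),
  including across the connector *a*.
- **Coordinations**: conjunct states become separate characters sharing the
  character name resolved from the first conjunct and its structure link;
  the conjunction word is recorded in the notes of later conjuncts
  (*u*→*o*, *e*→*y* normalised first). Emitting one character per conjunct
  (rather than one character with a coordinated value) is an interpretive
  choice: no printed record settles it, and separate characters are the
  more machine-usable form.
- **Numerals**: grammar `[(a-)] n[-m] [(-b)] [× ...] [unit] [de <noun>]`.
  Two dimensions are length then width, by botanical convention. Atypical
  bounds are open at the shared endpoint and stored numerically only.
  Bounds are `decimal.Decimal` so "3.3" round-trips textually. A sequence
  violating the grammar (e.g. an inverted range) is preserved verbatim as a
  plain character with a note. A single numeral yields a plain-valued
  character carrying the unit. One-dimension expressions take their name
  from a trailing "de <noun>" phrase via the glossary ("de altura" →
  height), defaulting to length.
- **Adverbs** go into the `constraint` of the state that follows them
  (child rule), else the preceding one; adverbs with no state in reach
  modify the current structure. A parenthetical aside becomes the
  constraint of the object built from the token before the parenthesis.
- **Determiners**: articles are consumed silently; quantifiers become
  structure constraints, attaching to the clause's current structure when
  their chunk has no entity ("varias por racimo").
- **Prepositions**: *con*/*sin* phrases produce an inner structure and a
  relation (negated for *sin*) from the clause's current structure;
  characters inside describe the inner structure. All other prepositional
  phrases — merged across consecutive prepositions — and all verbal phrases
  become spans attached to the most recent structure (deferred to the
  clause's main structure when none exists yet).
- **Association**: most recent structure agreeing in gender and number with
  the state's head token, else the clause's main structure, else a
  whole-plant pseudo-structure (`planta`, noted `estructura implícita`).
  The known failure mode — a state that agrees with a nearby substructure
  it does not logically describe — is reproduced, not patched; fixing it
  would require structure-hierarchy knowledge (ontologies), which is an
  explicit extension point, not part of this implementation.

Ids are assigned sequentially ("o1", "o2", ...) per description in creation
order, making runs reproducible and diffs stable. Re-annotating identical
input yields an identical model; there is no hidden global state.

## Serialization

One XML document per taxon: `statement` per clause (with its chunks),
structures with nested characters, relations, spans; fixed attribute order,
two-space indent, UTF-8 — byte-identical output for identical models, so
golden files work. `read_xml` restores the model (`read ∘ write` is the
identity up to object ordering); unknown attributes are kept in a
pass-through map with a warning. A JSON mirror of the same tree is
available behind a flag. The dialect is documented in `data/schema.rnc`.

## Synthetic corpus and evaluation

The generator emits one-clause records from a weighted pattern mixture. The
four classic chunk grammars keep their published frequencies (noun+state
17.5%, bare state 12.5%, measurement with unit and measured noun 9.8%,
two-dimension expression 4.2% — the printed percentages are adopted as
weights even though the accompanying raw counts are arithmetically
inconsistent with them); the remaining mass is spread evenly (14% each) over
four extension patterns that exercise coordination, adverb constraints,
con/sin relations and the non-adjacent agreement case (plural state skipping
a singular substructure). Adjective forms are inflected to their noun;
sampled families are forced to distinct character names so states never
merge accidentally. Gold annotations are built by construction, so scoring
the annotator against them is exact: matching is strict string equality on
normalised fields, with no partial credit. Precision with zero predictions
is reported as 0 with an `undefined_precision` flag.

Because the generator only emits in-grammar constructions, the pipeline must
score precision = recall = F-1 = 100% on all four aspects (structures,
characters, association, conjunctions) for every seed; the test suite checks
five seeds at 200 clauses each (about a second in total), and the
acceptance script uses the same check as a gate before reporting numbers.
What this does **not** show: robustness to out-of-grammar real text —
unknown vocabulary, complex prepositional semantics, and ontology-dependent
association are exactly the places where real corpora degrade, and the
reproduced Hydrangea-type association error is one documented instance.

A clause is *simple* with at most two structures, *complex* otherwise.

## Limitations

- Translation and character-name resolution use frozen local snapshots; no
  live glossary or ontology services are consulted, and `ontology_id` is
  carried but never populated.
- The lexicon covers common woody-plant vocabulary; out-of-vocabulary states
  are retained but typed `unknown_character`.
- Coordination of structures ("hojas y flores") is not modelled; only state
  coordination is.
- Only *con*/*sin* prepositional phrases are structured; the meaning of
  other prepositions and of verbs is out of scope by design.
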