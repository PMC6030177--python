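# morphex

Rule-based extraction of structured morphological data from plant taxonomic
descriptions written in Spanish.

Taxonomic descriptions are telegraphic: noun- and adjective-dense phrases
with almost no verbs ("hojas simples, alternas, 4-10 (-14) × 1-3.3 cm.,
elípticas, ..."). Each clause describes one botanical **structure** (leaves,
apex, base); comma-delimited chunks carry its **character states** (shape,
colouration, architecture, measurement ranges) and occasional
**relations** between structures ("semillas ... con arilo"). morphex turns a
table of (scientific name, description) rows into XML documents recording
structures, characters and relations, for downstream use in trait databases
and electronic keys.

## How it works

1. **Pre-processing** — quotes stripped, abbreviations expanded, "x" between
   numbers normalised to "×"; text segmented into clauses at `.` `:` `;`
   (periods inside decimals and after units never split) and into chunks at
   top-level commas.
2. **Tagging** — each token gets a role tag (E entity, A state, Z numeral,
   R adverb, D determiner, C conjunction, S preposition, U unit, G dimension
   symbol, V verb) from a bundled botanical lexicon plus a knowledge base
   grown by rule-driven bootstrapping (e.g. in "redondeada a cordada a
   subcordada", tokens chained by the preposition *a* share the state role
   of any known member).
3. **Glossary resolution** — Spanish states are translated to English and
   looked up in a character-name index: "elípticas" → *elliptic* →
   `arrangement` + `shape` (both emitted, flagged `Carácter repetido` for
   expert disambiguation); "simples" → *simple* → `architecture`.
4. **Semantic rules** — entities create structures (an apposed noun becomes
   a modifier: "frutos nueces"); states create characters; numeral ranges
   become `from`/`to` bounds with units and parenthesised atypical extremes
   ("9.5-19 (-22)" → to=19, atypical_to=22); two-dimension expressions split
   into length (before ×) and width (after ×); adverbs become `constraint`
   attributes; quantifiers modify structures; "con"/"sin" phrases become
   (negated) relations; other prepositional and verbal phrases are
   delimited as spans without losing text.
5. **Association** — a character links to the most recent preceding
   structure agreeing in grammatical gender and number with its head token
   (unmarked forms agree with anything), falling back to the clause's main
   structure. In the clause above, "glabras" (f. pl.) skips "base" (f. sg.)
   and "ápice" (m. sg.) and correctly lands on "hojas" (f. pl.). The
   heuristic's documented failure mode — a state agreeing with a nearer
   substructure it does not describe — is reproduced deliberately.

## Worked example

```python
from morphex import Annotator, write_xml

annotator = Annotator()
desc = annotator.annotate(
    "Quercus salicifolia",
    "hojas simples, alternas, 4-10 (-14) x 1-3.3 cm., elípticas, "
    "ápice acuminado, caudado o agudo, base caudada u obtusa, "
    "glabras o a veces con tricomas dispersos a lo largo de la vena "
    "central por el envés.",
)
write_xml(desc, "quercus.xml")
```

produces (abridged):

```xml
<structure id="o1" name="hojas" name_en="leaves">
  <character id="o2" name="architecture" value="simples"/>
  <character id="o3" name="arrangement" value="alternas"/>
  <character id="o4" name="length" value="4-10" char_type="range_value"
             from="4" to="10" from_unit="cm" to_unit="cm" atypical_to="14"/>
  <character id="o5" name="width" value="1-3.3" char_type="range_value"
             from="1" to="3.3" from_unit="cm" to_unit="cm"/>
  <character id="o6" name="arrangement" value="elípticas" notes="Carácter repetido"/>
  <character id="o7" name="shape" value="elípticas" notes="Carácter repetido"/>
  <character id="o15" name="pubescence" value="glabras"/>
</structure>
<structure id="o8" name="ápice" name_en="apex">
  <character id="o9" name="shape" value="acuminado"/>
  <character id="o10" name="shape" value="caudado"/>
  <character id="o11" name="shape" value="agudo" notes="conjunción: o"/>
</structure>
```

The leaf blade's dimensions (length 4–10 cm, rarely to 14; width 1–3.3 cm)
are attached to *hojas*; the coordinated shapes "caudado o agudo" both land
on *ápice*; the trailing prepositional phrase is delimited as a
`constraint_preposition` span while its entities (*tricomas*, *vena*,
*envés*) are still extracted for the association step.

## Command line

```bash
morphex annotate --input descriptions.tsv --out out/        # one XML per taxon
morphex fixtures --n 200 --seed 1 --out fixtures/           # synthetic corpus + gold
morphex evaluate --pred out/ --gold fixtures/gold/ --out scores.csv
```

`evaluate` reports precision/recall/F-1 for the four standard aspects:
identification of structures, character structuring, association of
characters to structures, and association of conjunctions.

## Layout

- `src/morphex/` — `preprocess`, `tagging`, `chunk_parser`, `glossary`,
  `annotator`, `xml_io`, `fixtures_eval`, `cli` over a shared `core_model`
- `src/morphex/data/` — bundled lexicon, gender-exception list, bilingual
  glossary, character-name index, abbreviation table, output schema
  (`schema.rnc`)
- `docs/methods.md` — model, rules, parameters and limitations
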