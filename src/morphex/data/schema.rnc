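# Description-document dialect written by morphex (RELAX NG compact syntax).
# One document per taxon; characters nest inside the structure they describe.

start = description

description = element description {
  attribute taxon_name { text },
  statement*
}

statement = element statement {
  attribute id { text },            # T{taxon}L{clause}
  attribute text { text },          # clause text after normalization
  attribute main_structure { text }?,
  chunk*, structure*, relation*, span*
}

chunk = element chunk {
  attribute id { text },            # T{taxon}L{clause}S{chunk}
  attribute text { text }
}

structure = element structure {
  attribute id { text },
  attribute name { text },
  attribute name_en { text }?,
  attribute constraint { text }?,
  attribute modifier { text }?,
  attribute ontology_id { text }?,
  attribute notes { text }?,
  character*
}

character = element character {
  attribute id { text },
  attribute name { text },
  attribute value { text },
  attribute char_type { "range_value" }?,   # absent means a plain value
  attribute from { text }?,
  attribute to { text }?,
  attribute from_unit { text }?,
  attribute to_unit { text }?,
  attribute atypical_from { text }?,
  attribute atypical_to { text }?,
  attribute constraint { text }?,
  attribute notes { text }?
}

relation = element relation {
  attribute id { text },
  attribute name { text },          # the preposition: "con" / "sin"
  attribute from { text },          # structure id
  attribute to { text },            # structure id
  attribute negated { "true" }?
}

span = element (constraint_preposition | constraint_verb | verb_string) {
  attribute text { text },
  attribute attached_to { text }    # structure or character id
}
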