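# Default relation rulebook: keyword classification rules per entity-pair
# family. Types within a group are checked in listed (priority) order; the
# fallback type of every group carries no keywords. Keywords are matched as
# stemmed token/phrase hits inside the sentence; the high-noise triggers
# listed under between_only only count when they occur between the two
# entity spans.
match_mode: stem
between_only: [and, between, no]
groups:
  disease_treatment:
    fallback: other
    types:
      - name: treatment
        keywords: [therapy, treating, cure, remedy, inhibit]
      - name: cause
        keywords: [induce, cause, side effect, influence, dynamic]
  compound_origin:
    fallback: other
    types:
      - name: entity_origin
        keywords: [include, contain]
      - name: advise
        keywords: [avoid, should not be]
      - name: int
        keywords: [interaction, and, between]
      - name: effect
        keywords: [enhance, against, demonstrated]
      - name: mechanism
        keywords: [metabolize, decrease, increase]
      - name: negative
        keywords: [no]
  compound_interaction:
    fallback: other
    types:
      - name: advise
        keywords: [avoid, should not be]
      - name: int
        keywords: [interaction, and, between]
      - name: effect
        keywords: [enhance, against, demonstrated]
      - name: mechanism
        keywords: [metabolize, decrease, increase]
      - name: negative
        keywords: [no]
  gene_association:
    fallback: other
    types:
      - name: positive_association
        keywords: [effect, induce, target]
      - name: negative_association
        keywords: [indifference, no]
families:
  CPM-Herb: compound_origin
  CPM-Ingredient: compound_origin
  CPM-Drug: compound_origin
  CPM-Chemical: compound_origin
  CPM-Symptom: disease_treatment
  CPM-Disease: disease_treatment
  CPM-Pathway: gene_association
  CPM-Gene: gene_association
  Herb-Ingredient: compound_origin
  Herb-Drug: compound_origin
  Herb-Chemical: compound_origin
  Herb-Symptom: disease_treatment
  Herb-Disease: disease_treatment
  Herb-Pathway: gene_association
  Herb-Gene: gene_association
  Ingredient-Drug: compound_interaction
  Ingredient-Chemical: compound_interaction
  Ingredient-Symptom: disease_treatment
  Ingredient-Disease: disease_treatment
  Ingredient-Pathway: gene_association
  Drug-Chemical: compound_interaction
  Drug-Symptom: disease_treatment
  Drug-Disease: disease_treatment
  Drug-Pathway: gene_association
  Drug-Gene: gene_association
  Chemical-Symptom: disease_treatment
  Chemical-Disease: disease_treatment
  Chemical-Pathway: gene_association
  Symptom-Disease: disease_treatment
  Symptom-Pathway: gene_association
  Disease-Gene: gene_association
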