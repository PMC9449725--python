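"""Resolve messy repository names against a Darwin Core reference taxonomy.

Builds a six-record taxonomy (one accepted synonym pair included), then
resolves four raw name strings: an exact match, a different author format,
a synonym, and a one-letter misspelling.
"""

from fernmatrix.taxonomy import (
    TaxonRecord, Taxonomy, match_name, resolve_accepted,
)

taxonomy = Taxonomy([
    TaxonRecord("ord", "Polypodiales", rank="order"),
    TaxonRecord("fam", "Aspleniaceae", rank="family", parent_id="ord"),
    TaxonRecord("gen", "Asplenium", rank="genus", parent_id="fam"),
    TaxonRecord("sp1", "Asplenium nidus", authorship="L.", rank="species", parent_id="gen"),
    TaxonRecord("sp2", "Asplenium trichomanes", authorship="L.", rank="species", parent_id="gen"),
    TaxonRecord("syn", "Neottopteris nidus", authorship="(L.) J. Sm.", rank="species",
                status="synonym", accepted_id="sp1", parent_id="gen"),
])

queries = [
    "Asplenium nidus L.",          # exact, same author
    "Asplenium nidus (Hook.) X.",  # same canonical name, odd authorship
    "Neottopteris nidus",          # synonym
    "Asplenium nidos",             # misspelled epithet
]

for raw in queries:
    match = match_name(raw, taxonomy)
    accepted = resolve_accepted(match, taxonomy)
    print(f"{raw:30s} -> {accepted}  ({match.match_kind}, edit distance {match.distance})")

# Every query lands on sp1 (Asplenium nidus): author formatting is tolerated,
# synonyms follow their acceptedNameUsageID pointer, and the misspelling is
# caught by bounded-edit-distance fuzzy matching.
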