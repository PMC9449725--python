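"""Rogue screening: flag accessions whose nearest neighbours are foreign.

Builds a toy all-by-all hit table in which one accession labelled as a
Ferna (Famaceae) actually matches three Gernaceae sequences best - the
signature of a misidentified or contaminated record.
"""

import pandas as pd

from fernmatrix.qc import HitTable, detect_rogues
from fernmatrix.taxonomy import TaxonRecord, Taxonomy

records = [TaxonRecord("ord", "Polypodiales", rank="order")]
ids = {}
for fam, genus, species in [
    ("Famaceae", "Ferna", ["alba", "nigra", "alta"]),
    ("Gernaceae", "Gerna", ["una", "dua", "tria"]),
]:
    records.append(TaxonRecord(fam, fam, rank="family", parent_id="ord"))
    records.append(TaxonRecord(genus, genus, rank="genus", parent_id=fam))
    for ep in species:
        sid = f"{genus}_{ep}"
        ids[sid] = sid
        records.append(TaxonRecord(sid, f"{genus} {ep}", rank="species", parent_id=genus))
taxonomy = Taxonomy(records)

species_of = {"Q_rogue": "Ferna_alba", "Q_clean": "Ferna_nigra",
              "F1": "Ferna_alta", "G1": "Gerna_una", "G2": "Gerna_dua", "G3": "Gerna_tria"}
rows = pd.DataFrame(
    [
        # the mislabelled accession: top three hits all Gernaceae
        ("Q_rogue", "G1", 480, 0.0), ("Q_rogue", "G2", 470, 0.0),
        ("Q_rogue", "G3", 460, 0.0), ("Q_rogue", "F1", 60, 0.0),
        # an honest accession: best hit is a family mate
        ("Q_clean", "F1", 450, 0.0), ("Q_clean", "G1", 70, 0.0),
        ("Q_clean", "G2", 65, 0.0), ("Q_clean", "G3", 60, 0.0),
    ],
    columns=["query", "subject", "score", "evalue"],
)

report = detect_rogues(HitTable(rows, species_of), taxonomy)
for q in ("Q_rogue", "Q_clean"):
    r = report.rows[q]
    print(f"{q}: status={r.status} (compared at {r.comparison_rank}; "
          f"query taxon {r.query_taxon}; top hits {', '.join(r.top_hit_taxa)})")

# Q_rogue is flagged because all three best matches belong to a different
# family; Q_clean survives because a single same-family hit in the top three
# is enough to keep it.
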