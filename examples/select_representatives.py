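"""Choose one set of sequences per species from competing accessions.

A species with three accessions: rbcL and atpB from the same voucher
specimen, plus a longer stand-alone rbcL from a different collection.  The
voucher pair may be concatenated (condition 2); selection rule S1 then
prefers the multi-locus, rbcL-containing set over the longer single rbcL.
"""

from fernmatrix.harvest import SequenceRecord
from fernmatrix.sampling import build_concat_groups, select_sanger_representative

records = [
    SequenceRecord("AC01", "rbcL", "SP1", "", "A" * 1300, voucher="smith 123"),
    SequenceRecord("AC02", "atpB", "SP1", "", "A" * 1100, voucher="smith 123"),
    SequenceRecord("AC03", "rbcL", "SP1", "", "A" * 1400, voucher="jones 9"),
]

groups = build_concat_groups(records, monophyly_map={})  # species not tested monophyletic
for g in groups:
    print(f"candidate [{g.basis:7s}] loci={[l for l, _ in g.members]} total={g.total_len}")

selection = select_sanger_representative(groups, records)
group, rule = selection.chosen["SP1"]
print(f"\nchosen by rule {rule}: {dict(group.members)} (total {group.total_len} bp)")

# Rule S1 fires because a candidate concatenation contains rbcL plus another
# locus; its 2400 bp total beats any single accession, including the longer
# 1400 bp rbcL, which would only win under rule S2 if no multi-locus
# candidate existed.
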