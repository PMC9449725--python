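"""Trim gappy columns and concatenate per-locus alignments.

Two toy locus alignments with partly overlapping taxon sets: the spacer
has one 20%-gappy column that a 5% threshold removes, and the taxon
missing the second locus receives a block of '?' in the supermatrix.
"""

from fernmatrix.supermatrix import Alignment, concatenate_supermatrix, trim_gappy_columns

rbcL = Alignment("rbcL", ["sp1", "sp2", "sp3"], ["ACGTACGT", "ACGAACGT", "ACGCACGA"])
spacer = Alignment(
    "trnL-trnF", ["sp1", "sp2", "sp3", "sp4", "sp5"],
    ["AAC-TT", "AACGTT", "AACGTA", "AACGTT", "AACGAT"],
)

trimmed, removed = trim_gappy_columns(spacer, 0.05)
print(f"spacer columns removed at 5% gap threshold: {removed} "
      f"({spacer.n_columns} -> {trimmed.n_columns} columns)")

bundle = concatenate_supermatrix([rbcL, trimmed])
print(f"supermatrix: {bundle.alignment.n_columns} columns x {len(bundle.alignment.taxa)} taxa")
print(f"partitions: {bundle.partitions}")
print(f"missing data: {bundle.missing_fraction:.1%} overall, per locus {bundle.locus_missing}")
for taxon in bundle.alignment.taxa:
    print(f"  {taxon}  {bundle.alignment.row_of(taxon)}")

# sp4/sp5 lack rbcL, so their first partition is all '?'; those cells (plus
# any N or -) are what the missing-data fraction counts.
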