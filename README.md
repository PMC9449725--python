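# fernmatrix

Taxonomy-aware curation of plastid sequence data into dated fern
supermatrices.

## The problem

Global species-level phylogenies of ferns are built by mining sequence
repositories: tens of thousands of plastid accessions — a few classic
PCR loci (*rbcL*, *atpA*, *atpB*, *matK*, *rps4*, and the *trnL*–*trnF*
and *rps4*–*trnS* spacers) plus a growing number of whole plastomes —
carrying inconsistent annotations, outdated synonyms, misspelled names,
misidentified material, and several competing sequences per species.
Between the raw repository dump and a dated tree sit a series of bespoke,
rule-based curation steps that are usually buried in one-off pipeline
scripts.  `fernmatrix` implements those steps as a tested, reusable
library:

- **taxonomy** — parse scientific names (author-format tolerant, hybrid
  and `aff.`/`cf.` aware) and resolve them against a Darwin Core reference
  taxonomy with exact-then-fuzzy matching and synonym resolution;
- **harvest** — admissibility filtering, the Sanger/plastome split at
  7,000 bp of source-accession length, per-genus reference databases, and
  baited extraction of target loci by local alignment (match +1,
  mismatch −1, gap −2);
- **qc** — rogue screening: an accession is flagged when its top three
  distinct matches in an all-by-all similarity search all belong to a
  different family (order for Cyatheales, suborder for Saccolomatineae;
  monotypic families exempt), plus MonoPhy-style taxon monophyly reports
  and curated include/exclude lists;
- **sampling** — species monophyly from gene trees, the three
  concatenation conditions (monophyletic species / shared voucher /
  single publication), and one-representative-per-species selection
  (rules S1–S3 maximising *rbcL* representation, longest-combined-length
  for plastomes);
- **supermatrix** — gap-threshold column trimming (strict `>`, trimAl
  semantics), per-family spacer subalignment planning for merge-capable
  aligners, and concatenation with partition table and missing-data
  accounting;
- **calibration** — outgroup rooting and trimming, fossil-to-node
  assignment (crown = MRCA, stem = its parent), oldest-fossil redundancy
  resolution, and emission of treePL configs (root fixed at 475 Ma, stem
  euphyllophytes ≥ 407.6 Ma, smoothing sweep 1e-12…1e-06);
- **fixtures** — a deterministic generator of complete synthetic input
  bundles with planted ground truth, so every stage is testable offline.

External heavy lifting (MAFFT, trimAl, FastTree, IQ-TREE, BLAST, treePL)
stays external: the package prepares their inputs and consumes their
outputs.

## Worked example

```python
from fernmatrix.fixtures import make_toy_dataset
from fernmatrix.pipeline import run_pipeline

bundle = make_toy_dataset(seed=1)     # 92 records, 4 loci, planted rogues
result = run_pipeline(bundle)
```

Running `python examples/end_to_end.py` prints:

```
records in: 92; inadmissible dropped: 4
rogues flagged: ['AC0011', 'AC0014', 'AC0040', 'AC0044', 'AC0048', 'AC0055']
  planted:       ['AC0011', 'AC0014', 'AC0040', 'AC0044', 'AC0048', 'AC0055']
species selected: 11 Sanger + 2 plastome
supermatrix: 1707 columns x 11 taxa, 27.9% missing
calibrations kept: ['CAL_crown_FAM1', 'CAL_crown_FAM2', 'CAL_crown_FAM3',
                    'CAL_crown_FAM4', 'CAL_stem_FAM0', 'CAL_stem_FAM3']
dating configs emitted for smoothing values: [1e-12, 1e-11, 1e-10, 1e-09, 1e-08, 1e-07, 1e-06]

pipeline output matches planted manifest: True
```

The four dropped records carry `cf.`/`aff.` annotations, a hybrid formula,
or an environmental-sample label; the six flagged accessions are exactly
the cross-family copies the generator planted; the 1707-column supermatrix
is the four trimmed locus alignments concatenated (three planted gappy
spacer columns removed at the 1% spacer threshold); and the kept
calibrations are the per-node oldest fossils, with the redundant younger
crown fossil superseded.  The other scripts in `examples/` demonstrate each
stage on its own.

A thin CLI wraps the same functions
(`fernmatrix --seed 1 --out-dir out run-pipeline`, plus `resolve-names`,
`extract-loci`, `filter-rogues`, `check-monophyly`, `select-sequences`,
`build-supermatrix`, `compile-calibrations`, `make-fixtures`); every run
writes a `run_log.json` with parameters and input digests.

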