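# Methods

This note documents the models, rules, and numerical choices behind
`fernmatrix`, and what its synthetic-data tests do and do not demonstrate.

## Name resolution

Raw name strings are parsed into a canonical part (genus, epithet,
optional infraspecific rank/epithet) and an authorship tail.  A
parenthetical leading the authorship marks a basionym author; `aff.`,
`cf.` and environmental-sample labels become annotations; a
multiplication sign (or standalone `x`) joining two names marks a hybrid
formula.  Hybrid taxa with standard (non-formula) names are admissible.

Matching proceeds in three stages: exact canonical + authorship, exact
canonical, then fuzzy.  The fuzzy stage minimises Levenshtein distance
(via edlib) over canonical names with the same number of name parts — a
trinomial never fuzzily collapses onto a binomial — bounded by
`max_distance`, which defaults to one edit per 10 characters capped at 3.
Author similarity (difflib ratio on case-folded, punctuation-stripped
strings) is only a tie-breaker among candidates at equal canonical
distance; unresolved ties are reported *ambiguous*, never auto-resolved.
Synonym resolution is a single `acceptedNameUsageID` hop; the validator
rejects synonym chains, dangling pointers, duplicate ids and parent
cycles, and all edits go through a transaction that re-validates.

The exact algorithm and thresholds of fuzzy taxonomic matchers vary
between tools; the contract implemented here (stage order, tie handling,
distance bound) is the package's own and is pinned by tests.

## Harvest

Admissibility drops environmental samples, `aff.`/`cf.` annotations and
hybrid formulas, each with a reason code.  Source accessions are split
into Sanger (≤ 7,000 bp) and plastome (> 7,000 bp) tiers — an empirical
cutoff, since repositories do not distinguish the two.  Sequence length
everywhere means ungapped length: characters outside {`?`, `N`, `-`}.

The packaged locus registry holds 79 plastid loci — 77 protein-coding
genes plus the trnL-trnF and rps4-trnS spacers — with the seven classic
Sanger loci (atpA, atpB, matK, rbcL, rps4 and the two spacers) flagged
`tier=both`.  The gene list is a representative, synthetic standard
plastid set; it is data, not a copy of any published table.

Baited extraction aligns a candidate locally against each per-genus
reference (both strands) and extracts the best-scoring span.  Scoring is
match +1, mismatch −1, gap −2 (linear), computed by Biopython's
`PairwiseAligner`; the test suite checks it against an independently
written Smith–Waterman dynamic program.  A hit is significant when score
≥ 50 and identity ≥ 0.7 — defaults chosen so that a ~50 bp exact match
passes while the best local alignment of unrelated few-hundred-bp
sequences (empirically ~30–40 under this scoring) does not.  Absence of a
significant match is a value, not an error.  An alternative path consumes
precomputed tabular (outfmt-6 dialect) hits and performs only the span
extraction; both paths agree on identical hits.  Coordinates are 0-based
half-open internally, 1-based inclusive in emitted tabular files.
Reference databases keep the single longest ungapped sequence per genus
per locus; all ties (length, score) break on lexicographic accession id.

## Rogue screening

For each query in an all-by-all similarity table: drop self-hits, collapse
multiple rows per subject to the subject's best row, rank subjects by
(score desc, evalue asc, subject id asc), and take the top three distinct
subjects.  The query is a rogue iff all three differ from it at the
comparison rank.  The comparison rank is family, overridden by a shipped
data table to order for Cyatheales and suborder for Saccolomatineae
(clusters of closely related small families where family-level comparison
gives false positives); a taxon lacking the override rank falls back to
its family name.  Species in monotypic families are exempt — their nearest
neighbours are necessarily foreign.  Queries with fewer than three usable
hits are *indeterminate* and never flagged: with so little evidence the
conservative choice is to keep the record.  Top-three is counted over
distinct subject accessions, not alignment rows, and conspecific hits are
retained as the strongest evidence of correct identity.  The result is
invariant to input row order.

Monophyly reports evaluate each taxon at or above genus: a taxon is
monophyletic when its sampled tips form a clade (rooted) or one side of a
split (unrooted); one sampled tip is *monotypic*, none is *unsampled*.
Intruders are reported as the distinct foreign taxa (at the evaluated
rank) under the taxon's MRCA, rooted evaluation only.

Curated lists: exclusion beats inclusion (conflicts logged); inclusion
marks accessions that selection must prefer over the automated rules.

## Concatenation and selection

Within a species, loci are concatenated only under three conditions, each
contributing *candidate* groups rather than short-circuiting the others:
(1) the species is monophyletic in every gene tree containing ≥ 2 of its
accessions (longest accession per locus; a species never so represented
is vacuously monophyletic), (2) accessions sharing a voucher specimen
(one candidate per voucher), (3) all of the species' accessions derive
from a single publication (strict: one shared key, absent fields never
match).  Unconcatenated accessions are always candidates.  Selection then
applies S1 (rbcL + ≥ 1 other locus, greatest total length), else S2
(longest rbcL), else S3 (greatest total length); curated preferences
override all three.  Ties break by (greater total length, more loci,
lexicographic accession tuple).  Plastome species take the single
specimen with the longest combined length over all plastome loci and are
removed from the Sanger pool.  The implementation is verified against an
independent literal transcription of the six rules over all 624
configurations of ≤ 3 accessions × 3 loci × the condition flags × tied
and untied lengths.

## Supermatrix

Trimming removes a column when its fraction of `-` rows **strictly
exceeds** the threshold (trimAl gap-threshold semantics): only `-` counts
as a gap for trimming, while `?`, `N` and `-` all count as missing for
the statistics.  Both 1% and 5% thresholds are in common use; which locus
class gets which is configuration, defaulting to 5% for coding loci and
1% for spacers (spacers are short and indel-rich, so aggressive trimming
is the safer default).  Spacer subalignment planning gives each family
with ≥ 3 sampled species its own sub-MSA; smaller families enter the
merge as singletons; unalignable families (default Anemiaceae, whose
spacers are saturated with indels) and outgroups are excluded with
reasons.  Concatenation takes the union of taxa (lexicographic order),
fills absent blocks with `?`, and emits 1-based inclusive partition
ranges in the widely parsed `DNA, locus = start-end` dialect.

## Calibration

The tree is rooted on the outgroup edge and the outgroup tip removed —
branch length on the outgroup edge cannot be divided objectively, so the
next-outermost lineages become the effective outgroup; tip-to-tip path
lengths among retained taxa are preserved.  Crown fossils bind the MRCA
of their sampled anchors; stem fossils bind that MRCA's parent (for one
sampled anchor, the tip's parent).  Unassignable calibrations (no
sampled anchors, or stem of the root) are reported, never silently
dropped.  Per node, only the oldest minimum age is informative: younger
fossils on the same node are superseded (ties by calibration id).  The
emitted config fixes the root at 475 Ma (min = max), adds a stem
lineage minimum of 407.6 Ma when its anchor taxa are sampled, writes one
config per smoothing value over 1e-12…1e-06 (decade steps), and a small
parser collects per-run chi-squared values to flag the minimum.  Configs
re-parse to the identical constraint list, and a validator checks any
dated tree against a config's minima and maxima.

## Synthetic data

`fixtures.make_toy_dataset(seed, n_families=5, n_species_per_family=4,
n_loci=4, rogue_rate=0.1)` is a pure function of its arguments.  The
default sizes give a bundle that exercises every rule — a monotypic
family, two Cyatheales families and a Saccolomatineae family for the rank
overrides, a family without rbcL for rule S3, planted synonyms,
misspellings and inadmissible names, two-accession species with planted
non-monophyly, voucher/publication sharing patterns, two plastome species
(one overlapping the Sanger set), and redundant plus unassignable
fossils — while keeping generation-plus-pipeline under a second.

Sequences evolve down a constructed species tree under a Jukes–Cantor
independent-sites process (branch lengths in expected substitutions;
spacers 1.2× faster).  Within-family divergence (~0.1 substitutions/site)
versus between-family divergence (> 0.8) guarantees that same-family
similarity always outranks cross-family similarity, so the planted rogue
set is exactly recoverable: hosts keep at least two clean family
neighbours per locus, donors provide at least three accessions, and one
plant per comparison-group-and-locus prevents interference.  Spacer
records carry three planted gap columns for the trimmer; coding records
are length-varied by truncation.  The manifest's expected representatives
come from a literal transcription of the selection rules applied to the
planted records; expected rogues, monophyly and constraint nodes are
recorded at planting time.

What passing these tests shows: the rules are implemented exactly as
specified, deterministically, end to end.  What they do not show:
behaviour on real repository data — real sequences have indels,
paralogues, chimeras, and rate heterogeneity the simulator omits
(no indel process, no alignment step, gene trees constructed rather than
estimated), and real name matching faces messier orthography than the
planted one-edit misspellings.  Significance thresholds tuned here
(min_score 50, min_identity 0.7) should be revisited for real data.

## Numerical and degenerate-input choices

- All randomness flows from explicit integer seeds; no global state.
- Every ordering ambiguity has a documented deterministic tie-break
  (lexicographic ids throughout).
- Empty taxonomies, empty alignments, empty constraint lists, missing
  outgroups and unparseable names raise structured errors; missing
  similarity matches, unassignable fossils and indeterminate rogue
  statuses are values.
- Problem sizes in tests (5-family bundles, ≤ 12-tip trees, ≤ 2 kb
  alignment oracles, 200-table rogue comparisons) were chosen so each
  suite section enumerates its rule space exhaustively while the whole
  suite runs in well under a minute of compute after JIT warm-up.

## Known limitations

- The aligner is linear-gap only; affine gap costs would better model
  real indels but are unnecessary for the extraction contract tested.
- `monophyly_report` reports intruder taxa but not outlier analysis of
  the taxon's own tips.
- The CLI's `select-sequences` works from flat files and therefore skips
  rogue screening and plastome handling; `run-pipeline` is the complete
  path.
- Smoothing selection runs the sweep and collects chi-squared values; the
  penalized-likelihood optimisation itself is external.
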