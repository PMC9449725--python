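"""Alignment trimming, spacer subalignment planning, and concatenation.

Per-locus alignments are trimmed by gap fraction (a column is removed when
the fraction of rows carrying "-" strictly exceeds the threshold; trimAl
gap-threshold semantics), then concatenated into a partitioned supermatrix
in which a taxon missing a locus receives a block of "?".  Spacer regions
cannot be aligned across distant families, so they are planned as per-family
subalignments to be merged by a merge-capable aligner: families with at
least ``min_group`` sampled species form their own sub-MSA, smaller
families enter as singletons, and unalignable families plus all outgroups
are excluded.

Thresholds are configuration: coding loci default to a 5% gap threshold
and spacers to 1%.  For missing-data statistics all of {"?", "N", "-"}
count as missing; only "-" counts as a gap for the trim rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .taxonomy import Taxonomy, lineage_of

__all__ = [
    "Alignment",
    "SubalignmentPlan",
    "SupermatrixBundle",
    "DEFAULT_GAP_THRESHOLDS",
    "trim_gappy_columns",
    "plan_spacer_subalignments",
    "concatenate_supermatrix",
    "write_alignment_fasta",
    "read_alignment_fasta",
    "write_phylip_relaxed",
    "write_partitions",
    "read_partitions",
    "write_merge_table",
]

MISSING_CHARS = set("?Nn-")
DEFAULT_GAP_THRESHOLDS = {"coding": 0.05, "spacer": 0.01}


@dataclass
class Alignment:
    locus: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicated taxa: {dupes}")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_of(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def missing_fraction(self) -> float:
        if not self.rows or self.n_columns == 0:
            return 0.0
        missing = sum(1 for row in self.rows for c in row if c in MISSING_CHARS)
        return missing / (len(self.rows) * self.n_columns)


def trim_gappy_columns(
    aln: Alignment, max_gap_fraction: float
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap ("-") fraction strictly exceeds the threshold.

    Returns the trimmed alignment and the 0-based indices of removed
    columns.  A column at exactly the threshold is kept.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if not aln.rows:
        raise ValueError("empty alignment")
    n = len(aln.rows)
    removed = [
        j
        for j in range(aln.n_columns)
        if sum(1 for row in aln.rows if row[j] == "-") / n > max_gap_fraction
    ]
    removed_set = set(removed)
    new_rows = [
        "".join(c for j, c in enumerate(row) if j not in removed_set) for row in aln.rows
    ]
    return Alignment(aln.locus, list(aln.taxa), new_rows), removed


# ---------------------------------------------------------------------------
# Spacer subalignment planning


@dataclass
class SubalignmentPlan:
    locus: str
    groups: dict[str, list[str]] = field(default_factory=dict)  # family -> species
    singletons: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (species, reason)


def plan_spacer_subalignments(
    species: Sequence[str],
    taxonomy: Taxonomy,
    locus: str = "trnL-trnF",
    min_group: int = 3,
    excluded_families: Iterable[str] = ("Anemiaceae",),
    outgroup_species: Iterable[str] = (),
    exclude_outgroups: bool = True,
) -> SubalignmentPlan:
    """Assign each species to a family sub-MSA, the singleton pool, or exclusion.

    Families with ``min_group`` or more sampled species get their own
    sub-MSA; smaller families' species are merged in as singletons.
    Families that cannot be aligned at all (default: Anemiaceae, whose
    spacers are saturated with indels) and outgroup species are excluded
    with reasons.
    """
    excluded_fams = set(excluded_families)
    outgroups = set(outgroup_species)
    plan = SubalignmentPlan(locus=locus)
    fam_of: dict[str, str] = {}
    by_family: dict[str, list[str]] = {}
    for sp in species:
        if exclude_outgroups and sp in outgroups:
            plan.excluded.append((sp, "outgroup"))
            continue
        fam = lineage_of(sp, taxonomy).family
        if fam in excluded_fams:
            plan.excluded.append((sp, "unalignable_family"))
            continue
        fam_of[sp] = fam
        by_family.setdefault(fam, []).append(sp)
    for fam in sorted(by_family):
        members = sorted(by_family[fam])
        if len(members) >= min_group:
            plan.groups[fam] = members
        else:
            plan.singletons.extend(members)
    plan.singletons.sort()
    return plan


def write_merge_table(plan: SubalignmentPlan, seq_order: Sequence[str], path: str | Path) -> None:
    """Merge table for a merge-capable aligner: per sub-MSA, one row of
    whitespace-separated 1-based sequence indices into ``seq_order``."""
    index = {sp: i + 1 for i, sp in enumerate(seq_order)}
    with open(path, "w") as fh:
        for fam in sorted(plan.groups):
            idx = [index[sp] for sp in plan.groups[fam] if sp in index]
            if idx:
                fh.write(" ".join(str(i) for i in idx) + f" # {fam}\n")
        # singletons carry no row: the merge step adds them individually


# ---------------------------------------------------------------------------
# Concatenation


@dataclass
class SupermatrixBundle:
    alignment: Alignment
    partitions: dict[str, tuple[int, int]]  # locus -> 1-based inclusive range
    locus_missing: dict[str, float]
    missing_fraction: float


def concatenate_supermatrix(
    alignments: Sequence[Alignment],
    locus_order: Optional[Sequence[str]] = None,
) -> SupermatrixBundle:
    """Concatenate per-locus alignments over the union of taxa.

    Absent locus blocks are filled with "?".  Taxon order is lexicographic;
    locus order follows ``locus_order`` (default: input order).  Partition
    ranges are 1-based inclusive, contiguous, and cover all columns.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    by_locus = {a.locus: a for a in alignments}
    if len(by_locus) != len(alignments):
        raise ValueError("duplicate locus names among alignments")
    order = list(locus_order) if locus_order is not None else [a.locus for a in alignments]
    unknown = [l for l in order if l not in by_locus]
    if unknown:
        raise ValueError(f"locus_order names absent from alignments: {unknown}")

    taxa = sorted({t for a in alignments for t in a.taxa})
    parts: dict[str, tuple[int, int]] = {}
    locus_missing: dict[str, float] = {}
    col = 0
    rows = {t: [] for t in taxa}
    for locus in order:
        aln = by_locus[locus]
        width = aln.n_columns
        parts[locus] = (col + 1, col + width)
        col += width
        idx = {t: i for i, t in enumerate(aln.taxa)}
        missing_cells = 0
        for t in taxa:
            if t in idx:
                row = aln.rows[idx[t]]
            else:
                row = "?" * width
            missing_cells += sum(1 for c in row if c in MISSING_CHARS)
            rows[t].append(row)
        locus_missing[locus] = missing_cells / (len(taxa) * width) if width else 0.0

    concat = Alignment("supermatrix", taxa, ["".join(rows[t]) for t in taxa])
    total_cells = len(taxa) * concat.n_columns
    overall = (
        sum(1 for r in concat.rows for c in r if c in MISSING_CHARS) / total_cells
        if total_cells
        else 0.0
    )
    return SupermatrixBundle(concat, parts, locus_missing, overall)


# ---------------------------------------------------------------------------
# I/O

_WRAP = 80


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n")
            for i in range(0, len(row), _WRAP):
                fh.write(row[i : i + _WRAP] + "\n")


def read_alignment_fasta(path: str | Path, locus: str = "") -> Alignment:
    taxa: list[str] = []
    rows: list[str] = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if taxa:
                    rows.append("".join(cur))
                taxa.append(line[1:].strip())
                cur = []
            elif line:
                cur.append(line)
    if taxa:
        rows.append("".join(cur))
    return Alignment(locus or Path(path).stem, taxa, rows)


def write_phylip_relaxed(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(aln.taxa)} {aln.n_columns}\n")
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f"{taxon}  {row}\n")


def write_partitions(partitions: dict[str, tuple[int, int]], path: str | Path) -> None:
    """The widely parsed "DNA, <locus> = <start>-<end>" dialect."""
    with open(path, "w") as fh:
        for locus, (start, end) in partitions.items():
            fh.write(f"DNA, {locus} = {start}-{end}\n")


def read_partitions(path: str | Path) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            head, rng = line.split("=")
            locus = head.split(",", 1)[1].strip()
            start, end = rng.strip().split("-")
            out[locus] = (int(start), int(end))
    return out
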