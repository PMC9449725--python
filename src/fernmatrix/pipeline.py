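"""End-to-end orchestration: raw records to supermatrix and dating config.

Stages, in order: admissibility filtering on raw names; taxonomic name
resolution against the reference taxonomy; Sanger/plastome tier split on
source-accession length; rogue screening of Sanger accessions from the
all-by-all hit table; plastome representative selection (species chosen
there leave the Sanger pool); species-monophyly classification from gene
trees; candidate concatenation and per-species representative selection;
per-locus alignment assembly, gap trimming and supermatrix concatenation;
outgroup rooting/trimming of the species tree and compilation of fossil
calibrations into a dating configuration sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy

from . import calibration as cal
from .fixtures import FixtureBundle
from .harvest import (
    DEFAULT_LOCI,
    SequenceRecord,
    classify_tier,
    filter_admissible,
    normalize_voucher,
)
from .qc import HitTable, RogueReport, detect_rogues
from .sampling import (
    GeneTreeSet,
    SelectionResult,
    build_concat_groups,
    classify_species_monophyly,
    select_plastome_representative,
    select_sanger_representative,
)
from .supermatrix import (
    Alignment,
    DEFAULT_GAP_THRESHOLDS,
    SupermatrixBundle,
    concatenate_supermatrix,
    trim_gappy_columns,
)
from .taxonomy import NameParseError, ResolutionError, match_name, resolve_accepted

__all__ = ["PipelineResult", "run_pipeline"]

_CATEGORY = {l.name: l.category for l in DEFAULT_LOCI}


@dataclass
class PipelineResult:
    resolution: dict[str, str] = field(default_factory=dict)  # accession -> species_id
    dropped: dict[str, str] = field(default_factory=dict)  # accession -> reason
    rogues: Optional[RogueReport] = None
    monophyly: dict[str, bool] = field(default_factory=dict)
    sanger_selection: Optional[SelectionResult] = None
    plastome_selection: Optional[SelectionResult] = None
    alignments: dict[str, Alignment] = field(default_factory=dict)
    supermatrix: Optional[SupermatrixBundle] = None
    assignments_kept: list = field(default_factory=list)
    superseded: list = field(default_factory=list)
    unassignable: list = field(default_factory=list)
    constraints: list = field(default_factory=list)
    configs: dict[float, str] = field(default_factory=dict)


def run_pipeline(
    bundle: FixtureBundle,
    gap_thresholds: dict[str, float] = DEFAULT_GAP_THRESHOLDS,
) -> PipelineResult:
    result = PipelineResult()
    taxonomy = bundle.taxonomy

    # 1. admissibility on raw names
    kept, dropped = filter_admissible(bundle.records)
    for rec, reason in dropped:
        result.dropped[rec.accession] = reason

    # 2. name resolution
    resolved: list[SequenceRecord] = []
    for rec in kept:
        try:
            m = match_name(rec.raw_name, taxonomy)
            sp = resolve_accepted(m, taxonomy)
        except (NameParseError, ResolutionError):
            result.dropped[rec.accession] = "unresolved"
            continue
        result.resolution[rec.accession] = sp
        resolved.append(
            replace(rec, species_id=sp, voucher=normalize_voucher(rec.voucher))
        )

    # 3. tier split on source-accession length
    sanger = []
    plastome = []
    for rec in resolved:
        tier = classify_tier(bundle.source_length.get(rec.accession, len(rec.seq)))
        rec = replace(rec, tier=tier)
        (sanger if tier == "sanger" else plastome).append(rec)

    # 4. rogue screen over the all-by-all table
    species_of = {r.accession: r.species_id for r in sanger}
    table = HitTable(bundle.hit_rows, species_of)
    result.rogues = detect_rogues(table, taxonomy)
    flagged = result.rogues.flagged
    sanger = [r for r in sanger if r.accession not in flagged]

    # 5. plastome representatives; their species leave the Sanger pool
    result.plastome_selection = select_plastome_representative(plastome)
    plastome_species = set(result.plastome_selection.chosen)
    sanger = [r for r in sanger if r.species_id not in plastome_species]

    # 6. species monophyly from gene trees (clean accessions only)
    trees = {}
    tree_species = {}
    for locus, nwk in bundle.gene_trees.items():
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        keep_tips = []
        for leaf in tree.leaf_node_iter():
            acc = leaf.taxon.label
            if acc in flagged:
                continue
            if acc in result.resolution:
                keep_tips.append(acc)
                tree_species[acc] = result.resolution[acc]
        if len(keep_tips) < 2:
            continue
        if len(keep_tips) < sum(1 for _ in tree.leaf_node_iter()):
            tree.retain_taxa_with_labels(keep_tips)
        trees[locus] = tree
    if trees:
        gts = GeneTreeSet(trees, tree_species)
        result.monophyly = classify_species_monophyly(gts)

    # 7. candidate groups and representative selection
    groups = build_concat_groups(sanger, result.monophyly)
    result.sanger_selection = select_sanger_representative(groups, sanger)

    # 8. per-locus alignments from the chosen representatives
    chosen_rec: dict[tuple[str, str], SequenceRecord] = {}
    by_key = {(r.locus, r.accession): r for r in sanger}
    for sp, (group, _) in result.sanger_selection.chosen.items():
        for locus, acc in group.members:
            chosen_rec[(locus, sp)] = by_key[(locus, acc)]
    locus_order = [l for l in bundle.sanger_loci]
    trimmed: list[Alignment] = []
    for locus in locus_order:
        entries = sorted(
            (sp, rec) for (l, sp), rec in chosen_rec.items() if l == locus
        )
        if not entries:
            continue
        width = max(len(rec.seq) for _, rec in entries)
        taxa = [sp for sp, _ in entries]
        rows = [rec.seq + "?" * (width - len(rec.seq)) for _, rec in entries]
        aln = Alignment(locus, taxa, rows)
        threshold = gap_thresholds.get(_CATEGORY.get(locus, "coding"), 0.05)
        aln, _removed = trim_gappy_columns(aln, threshold)
        result.alignments[locus] = aln
        trimmed.append(aln)
    if trimmed:
        result.supermatrix = concatenate_supermatrix(
            trimmed, [a.locus for a in trimmed]
        )

    # 9. calibration compilation on the rooted, outgroup-trimmed species tree
    tree = dendropy.Tree.get(data=bundle.species_tree, schema="newick")
    rooted = cal.root_and_trim(tree, bundle.outgroup_label)
    assignments, result.unassignable = cal.assign_calibration_nodes(
        rooted, bundle.calibrations
    )
    result.assignments_kept, result.superseded = cal.resolve_redundant_calibrations(
        assignments
    )
    result.constraints = cal.build_constraints(
        rooted,
        result.assignments_kept,
        fix_root=True,
        euphyllophyte_anchors=bundle.euphyllophyte_anchors,
    )
    numsites = result.supermatrix.alignment.n_columns if result.supermatrix else 1
    result.configs = cal.write_treepl_config(
        result.constraints,
        "dated.tre",
        numsites=max(1, numsites),
        tree_tips={l.taxon.label for l in rooted.leaf_node_iter()},
    )
    return result
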