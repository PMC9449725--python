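"""Rogue-accession screening and taxon monophyly reporting.

Misidentified, contaminated or otherwise erroneous repository sequences
("rogues") betray themselves by their nearest similarity neighbours: an
accession whose top hits in an all-by-all search all belong to a different
family than its own label is almost certainly mislabelled.  The screen
compares taxa at family rank by default; orders containing several closely
related small families are compared at a higher rank via an override table
(shipped defaults: Cyatheales at order rank, Saccolomatineae at suborder
rank) to avoid false positives, and species in monotypic families are
exempt because the rule cannot distinguish them from their nearest
relatives.

The monophyly report supports the iterative curation loop: after each round
of tree building, taxa at or above genus rank are checked for monophyly and
intruding tips are listed so curators can spot remaining rogues or
taxonomy defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
import pandas as pd

from .harvest import SequenceRecord
from .taxonomy import Lineage, Taxonomy, lineage_of

__all__ = [
    "HitTable",
    "RogueRow",
    "RogueReport",
    "MonophylyStatus",
    "MonophylyReport",
    "DEFAULT_RANK_OVERRIDES",
    "detect_rogues",
    "monophyly_report",
    "tip_set_is_monophyletic",
    "apply_curated_lists",
]

# taxon name -> rank to compare at, instead of family
DEFAULT_RANK_OVERRIDES: dict[str, str] = {
    "Cyatheales": "order",
    "Saccolomatineae": "suborder",
}


@dataclass
class HitTable:
    """All-by-all similarity hits plus the accession -> species map."""

    rows: pd.DataFrame  # columns: query, subject, score, evalue
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        required = {"query", "subject", "score", "evalue"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
        if (self.rows["score"] < 0).any():
            raise ValueError("hit scores must be non-negative")


@dataclass(frozen=True)
class RogueRow:
    query: str
    flagged: bool
    comparison_rank: str  # family | order | suborder
    query_taxon: str
    top_hit_taxa: tuple[str, ...]
    status: str  # clean | rogue | indeterminate | exempt_monotypic


@dataclass
class RogueReport:
    rows: dict[str, RogueRow] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> set[str]:
        return {q for q, r in self.rows.items() if r.flagged}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query": r.query,
                    "status": r.status,
                    "flagged": r.flagged,
                    "comparison_rank": r.comparison_rank,
                    "query_taxon": r.query_taxon,
                    "top_hit_taxa": ";".join(r.top_hit_taxa),
                }
                for _, r in sorted(self.rows.items())
            ],
            columns=["query", "status", "flagged", "comparison_rank", "query_taxon", "top_hit_taxa"],
        )


def _taxon_at_rank(lin: Lineage, rank: str) -> Optional[str]:
    return {
        "genus": lin.genus,
        "family": lin.family,
        "order": lin.order,
        "suborder": lin.suborder,
    }[rank]


def _comparison_rank(lin: Lineage, overrides: dict[str, str]) -> str:
    # an override keyed on any name in the lineage redirects the comparison
    for name in (lin.order, lin.suborder, lin.family):
        if name and name in overrides:
            return overrides[name]
    return "family"


def detect_rogues(
    hits: HitTable,
    taxonomy: Taxonomy,
    overrides: Optional[dict[str, str]] = None,
) -> RogueReport:
    """Flag queries whose top three best matches are all taxonomically foreign.

    Per query: self-hits (same accession) are dropped, remaining hits are
    collapsed to one best row per distinct subject accession and ranked by
    (score desc, evalue asc, subject asc); the query is a rogue iff three
    usable hits exist and all three subjects differ from the query at the
    comparison rank.  Queries with fewer than three usable hits are
    *indeterminate*, never flagged; queries in monotypic families are
    *exempt*.  The result does not depend on input row order.
    """
    if overrides is None:
        overrides = DEFAULT_RANK_OVERRIDES
    report = RogueReport()
    lineages: dict[str, Optional[Lineage]] = {}

    def lin_for(acc: str) -> Optional[Lineage]:
        sp = hits.species_of.get(acc)
        if sp is None:
            return None
        if sp not in lineages:
            try:
                lineages[sp] = lineage_of(sp, taxonomy)
            except (KeyError, ValueError):
                lineages[sp] = None
        return lineages[sp]

    queries = sorted(hits.rows["query"].unique())
    for q in queries:
        qlin = lin_for(q)
        if qlin is None:
            report.unmapped.append(q)
            continue
        rank = _comparison_rank(qlin, overrides)
        qtaxon = _taxon_at_rank(qlin, rank) or qlin.family
        if qlin.is_monotypic_family:
            report.rows[q] = RogueRow(q, False, rank, qtaxon, (), "exempt_monotypic")
            continue
        sub = hits.rows[(hits.rows["query"] == q) & (hits.rows["subject"] != q)]
        # best row per distinct subject, then rank subjects
        best: dict[str, tuple[float, float]] = {}
        for row in sub.itertuples(index=False):
            key = (-float(row.score), float(row.evalue))
            if row.subject not in best or key < best[row.subject]:
                best[row.subject] = key
        usable = []
        for subj in best:
            slin = lin_for(subj)
            if slin is None:
                continue  # unmapped subjects are excluded from the ranking
            usable.append((best[subj][0], best[subj][1], subj, slin))
        usable.sort(key=lambda t: (t[0], t[1], t[2]))
        top3 = usable[:3]
        top_taxa = tuple((_taxon_at_rank(l, rank) or l.family) for *_, l in top3)
        if len(top3) < 3:
            report.rows[q] = RogueRow(q, False, rank, qtaxon, top_taxa, "indeterminate")
            continue
        foreign = all(t != qtaxon for t in top_taxa)
        status = "rogue" if foreign else "clean"
        report.rows[q] = RogueRow(q, foreign, rank, qtaxon, top_taxa, status)
    return report


# ---------------------------------------------------------------------------
# Monophyly


@dataclass(frozen=True)
class MonophylyStatus:
    taxon: str
    rank: str
    status: str  # monophyletic | non_monophyletic | monotypic | unsampled
    tips: tuple[str, ...] = ()
    intruders: tuple[str, ...] = ()
    outliers: tuple[str, ...] = ()


@dataclass
class MonophylyReport:
    statuses: dict[str, MonophylyStatus] = field(default_factory=dict)

    def status_of(self, taxon: str) -> str:
        return self.statuses[taxon].status

    def non_monophyletic(self) -> list[str]:
        return sorted(t for t, s in self.statuses.items() if s.status == "non_monophyletic")


def _clade_leafsets_rooted(tree: dendropy.Tree) -> list[frozenset[str]]:
    out = []
    for node in tree.preorder_node_iter():
        out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def tip_set_is_monophyletic(tree: dendropy.Tree, tips: set[str], rooted: bool) -> bool:
    """Is ``tips`` a clade (rooted) or one side of a split (unrooted)?"""
    all_tips = {l.taxon.label for l in tree.leaf_node_iter()}
    if not tips <= all_tips:
        raise ValueError(f"tips not in tree: {sorted(tips - all_tips)}")
    if len(tips) <= 1 or tips == all_tips:
        return True
    clades = set(_clade_leafsets_rooted(tree))
    target = frozenset(tips)
    if rooted:
        return target in clades
    return target in clades or frozenset(all_tips - tips) in clades


def monophyly_report(
    tree: dendropy.Tree,
    taxonomy: Taxonomy,
    ranks: Iterable[str] = ("genus", "family", "suborder", "order"),
    tip_to_species: Optional[dict[str, str]] = None,
    rooted: bool = True,
) -> MonophylyReport:
    """Monophyly of every taxon at the given ranks, given a species tree.

    Tree tips are species ids unless ``tip_to_species`` maps tip labels to
    species ids.  A taxon with one sampled tip is *monotypic*; with none,
    *unsampled*.  Intruder tips (foreign tips under the taxon's MRCA) are
    reported for rooted evaluation only.
    """
    tip_labels = [l.taxon.label for l in tree.leaf_node_iter()]
    species_of = tip_to_species or {t: t for t in tip_labels}
    bad = [t for t in tip_labels if t not in species_of]
    if bad:
        raise ValueError(f"tips with no species mapping: {sorted(bad)}")
    lin_of: dict[str, Lineage] = {}
    offenders = []
    for t in tip_labels:
        try:
            lin_of[t] = lineage_of(species_of[t], taxonomy)
        except (KeyError, ValueError):
            offenders.append(t)
    if offenders:
        raise ValueError(f"tips with unresolvable species: {sorted(offenders)}")

    # taxon name -> rank + tip members
    members: dict[str, tuple[str, set[str]]] = {}
    rankset = set(ranks)
    for t, lin in lin_of.items():
        for rank in ("genus", "family", "suborder", "order"):
            if rank not in rankset:
                continue
            name = _taxon_at_rank(lin, rank)
            if not name:
                continue
            members.setdefault(name, (rank, set()))[1].add(t)

    report = MonophylyReport()
    all_tips = set(tip_labels)
    for name in sorted(members):
        rank, tips = members[name]
        if len(tips) == 0:
            report.statuses[name] = MonophylyStatus(name, rank, "unsampled")
            continue
        if len(tips) == 1:
            report.statuses[name] = MonophylyStatus(name, rank, "monotypic", tuple(sorted(tips)))
            continue
        mono = tip_set_is_monophyletic(tree, tips, rooted=rooted)
        intruders: tuple[str, ...] = ()
        if rooted and not mono:
            # intruders are reported as the distinct foreign taxa (at the
            # same rank) found under the taxon's MRCA, MonoPhy-style
            mrca = tree.mrca(taxon_labels=sorted(tips))
            under = {l.taxon.label for l in mrca.leaf_iter()}
            foreign = under - tips
            intruder_taxa = set()
            for t in sorted(foreign):
                other = _taxon_at_rank(lin_of[t], rank)
                intruder_taxa.add(other if other else t)
            intruders = tuple(sorted(intruder_taxa))
        report.statuses[name] = MonophylyStatus(
            name, rank,
            "monophyletic" if mono else "non_monophyletic",
            tuple(sorted(tips)), intruders,
        )
    return report


# ---------------------------------------------------------------------------
# Curated include / exclude lists


def _ids_for(rec: SequenceRecord) -> set[str]:
    return {rec.accession, f"{rec.accession}|{rec.locus}"}


def apply_curated_lists(
    records: Iterable[SequenceRecord],
    exclude_list: Iterable[str] = (),
    include_list: Iterable[str] = (),
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]], set[str], list[str]]:
    """Apply expert-curated exclusion and preferential-inclusion lists.

    Returns (kept records, dropped-with-reason, preferred accession ids,
    conflict log).  Exclusion beats inclusion; inclusion marks accessions
    that downstream selection must prefer over automated choices.  Ids may
    be plain accessions or ``accession|locus``.
    """
    exclude = set(exclude_list)
    include = set(include_list)
    conflicts = sorted(exclude & include)
    records = list(records)
    kept: list[SequenceRecord] = []
    dropped: list[tuple[SequenceRecord, str]] = []
    preferred: set[str] = set()
    seen_ids: set[str] = set()
    for rec in records:
        ids = _ids_for(rec)
        seen_ids |= ids
        if ids & exclude:
            dropped.append((rec, "curated_rogue"))
            continue
        if ids & include:
            preferred.add(rec.accession)
        kept.append(rec)
    missing = sorted((exclude | include) - seen_ids)
    log = [f"conflict (excluded wins): {c}" for c in conflicts]
    log += [f"listed id not present in records: {m}" for m in missing]
    return kept, dropped, preferred, log
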