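"""Per-species concatenation and representative selection.

Selecting "the longest sequence per locus per species" across repository
accessions silently builds chimeric taxa when species are non-monophyletic
or accessions are misidentified.  Loci are therefore only concatenated
across accessions when one of three conditions holds:

1. the species is monophyletic in every gene tree containing two or more
   of its accessions (then the longest accession per locus is taken);
2. the accessions share a voucher specimen (same physical organism);
3. all of the species' accessions come from a single publication.

Each condition that applies contributes a *candidate* concatenation group;
unconcatenated single accessions are always candidates too.  One final
representative per species is then chosen, maximising representation of
rbcL (historically the most sequenced fern locus):

- S1: among groups containing rbcL plus at least one other locus, the one
  with the greatest total sequence length;
- S2: otherwise, among rbcL-containing candidates, the longest rbcL;
- S3: otherwise, the candidate with the greatest total length.

Whole-plastome specimens bypass these rules: per species, the single
specimen with the longest combined length over all plastome loci wins, and
species chosen there are excluded from the Sanger selection.

All sequence lengths exclude missing bases ("?", "N", "-").  Every tie
breaks deterministically by (greater total length, more loci, lexicographic
accession tuple).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

from .harvest import SequenceRecord, ungapped_length
from .qc import tip_set_is_monophyletic

__all__ = [
    "GeneTreeSet",
    "ConcatGroup",
    "SelectionResult",
    "classify_species_monophyly",
    "build_concat_groups",
    "select_sanger_representative",
    "select_plastome_representative",
]


@dataclass
class GeneTreeSet:
    """One unrooted gene tree per locus, tips labelled by accession."""

    trees: dict[str, dendropy.Tree]
    species_of: dict[str, str]  # accession -> species_id

    def __post_init__(self):
        for locus, tree in self.trees.items():
            for leaf in tree.leaf_node_iter():
                if leaf.taxon.label not in self.species_of:
                    raise ValueError(
                        f"tip {leaf.taxon.label!r} in {locus} gene tree has no species mapping"
                    )


@dataclass(frozen=True)
class ConcatGroup:
    species_id: str
    basis: str  # monophyly | voucher | publication | single
    members: tuple[tuple[str, str], ...]  # sorted (locus, accession) pairs
    total_len: int
    has_rbcL: bool

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.members)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(sorted({a for _, a in self.members}))


@dataclass
class SelectionResult:
    chosen: dict[str, tuple[ConcatGroup, str]] = field(default_factory=dict)
    # species_id -> (group, rule in {S1, S2, S3, plastome, curated})
    unselectable: list[str] = field(default_factory=list)

    def rule_of(self, species_id: str) -> str:
        return self.chosen[species_id][1]

    def to_rows(self) -> list[dict]:
        rows = []
        for sp in sorted(self.chosen):
            group, rule = self.chosen[sp]
            for locus, acc in group.members:
                rows.append({"species_id": sp, "rule": rule, "locus": locus, "accession": acc})
        return rows


# ---------------------------------------------------------------------------


def classify_species_monophyly(gene_trees: GeneTreeSet) -> dict[str, bool]:
    """Species -> monophyletic in every gene tree with >=2 of its accessions.

    A species never represented by two accessions in any single tree is
    vacuously monophyletic.
    """
    result: dict[str, bool] = {sp: True for sp in set(gene_trees.species_of.values())}
    for locus in sorted(gene_trees.trees):
        tree = gene_trees.trees[locus]
        by_species: dict[str, set[str]] = {}
        for leaf in tree.leaf_node_iter():
            acc = leaf.taxon.label
            by_species.setdefault(gene_trees.species_of[acc], set()).add(acc)
        for sp, accs in by_species.items():
            if len(accs) < 2 or not result[sp]:
                continue
            if not tip_set_is_monophyletic(tree, accs, rooted=False):
                result[sp] = False
    return result


def _longest_per_locus(records: list[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Per locus, the record with greatest ungapped length (tie: accession asc)."""
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        cur = best.get(rec.locus)
        if cur is None:
            best[rec.locus] = rec
            continue
        key_new = (-ungapped_length(rec.seq), rec.accession)
        key_cur = (-ungapped_length(cur.seq), cur.accession)
        if key_new < key_cur:
            best[rec.locus] = rec
    return best


def _make_group(species_id: str, basis: str, per_locus: dict[str, SequenceRecord]) -> ConcatGroup:
    members = tuple(sorted((locus, rec.accession) for locus, rec in per_locus.items()))
    total = sum(ungapped_length(rec.seq) for rec in per_locus.values())
    return ConcatGroup(species_id, basis, members, total, "rbcL" in per_locus)


def build_concat_groups(
    records: Iterable[SequenceRecord],
    monophyly_map: dict[str, bool],
) -> list[ConcatGroup]:
    """All candidate concatenation groups, per species, for the three conditions.

    Candidates are emitted for every condition that applies plus one group
    per unconcatenated source accession; selection among them happens in
    :func:`select_sanger_representative`.  Missing voucher/publication
    fields never satisfy the voucher/publication conditions.
    """
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)

    groups: list[ConcatGroup] = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        # condition 1: monophyletic species -> longest accession per locus
        if monophyly_map.get(sp, False):
            groups.append(_make_group(sp, "monophyly", _longest_per_locus(recs)))
        # condition 2: accessions sharing a voucher, one candidate per voucher
        by_voucher: dict[str, list[SequenceRecord]] = {}
        for rec in recs:
            if rec.voucher:
                by_voucher.setdefault(rec.voucher, []).append(rec)
        for voucher in sorted(by_voucher):
            groups.append(_make_group(sp, "voucher", _longest_per_locus(by_voucher[voucher])))
        # condition 3: ALL the species' accessions from one publication
        pubs = {rec.publication for rec in recs}
        if len(pubs) == 1 and None not in pubs and "" not in pubs:
            groups.append(_make_group(sp, "publication", _longest_per_locus(recs)))
        # unconcatenated: one candidate per source accession
        by_acc: dict[str, list[SequenceRecord]] = {}
        for rec in recs:
            by_acc.setdefault(rec.accession, []).append(rec)
        for acc in sorted(by_acc):
            groups.append(_make_group(sp, "single", _longest_per_locus(by_acc[acc])))
    return groups


def _tiebreak_key(group: ConcatGroup):
    return (-group.total_len, -len(group.members), group.accessions)


def _rbcL_len(group: ConcatGroup, length_of: dict[tuple[str, str], int]) -> int:
    for locus, acc in group.members:
        if locus == "rbcL":
            return length_of[(locus, acc)]
    return 0


def select_sanger_representative(
    groups: Iterable[ConcatGroup],
    records: Iterable[SequenceRecord],
    curated_preferences: Iterable[str] = (),
) -> SelectionResult:
    """One representative group per species by rules S1/S2/S3.

    ``curated_preferences`` is a set of accession ids that must be chosen
    for their species when any candidate group contains them (rule
    ``curated``), overriding the automated rules.
    """
    length_of = {(r.locus, r.accession): ungapped_length(r.seq) for r in records}
    preferred = set(curated_preferences)
    by_species: dict[str, list[ConcatGroup]] = {}
    for g in groups:
        by_species.setdefault(g.species_id, []).append(g)

    result = SelectionResult()
    for sp in sorted(by_species):
        cands = sorted(by_species[sp], key=_tiebreak_key)
        if not cands:
            result.unselectable.append(sp)
            continue
        curated = [g for g in cands if set(g.accessions) & preferred]
        if curated:
            # prefer the candidate covering the most preferred accessions
            curated.sort(key=lambda g: (-len(set(g.accessions) & preferred), _tiebreak_key(g)))
            result.chosen[sp] = (curated[0], "curated")
            continue
        s1 = [g for g in cands if g.has_rbcL and len(g.members) >= 2]
        if s1:
            result.chosen[sp] = (min(s1, key=_tiebreak_key), "S1")
            continue
        s2 = [g for g in cands if g.has_rbcL]
        if s2:
            s2.sort(key=lambda g: (-_rbcL_len(g, length_of), _tiebreak_key(g)))
            result.chosen[sp] = (s2[0], "S2")
            continue
        result.chosen[sp] = (min(cands, key=_tiebreak_key), "S3")
    return result


def select_plastome_representative(
    plastome_records: Iterable[SequenceRecord],
) -> SelectionResult:
    """Per species, the specimen with the longest combined plastome length.

    Each source accession is one specimen (whole-plastome records all come
    from a single voucher).  Ties break on lexicographic accession id.
    """
    by_specimen: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in plastome_records:
        by_specimen.setdefault((rec.species_id, rec.accession), []).append(rec)

    per_species: dict[str, list[tuple[int, str, list[SequenceRecord]]]] = {}
    for (sp, acc), recs in by_specimen.items():
        total = sum(ungapped_length(r.seq) for r in recs)
        per_species.setdefault(sp, []).append((total, acc, recs))

    result = SelectionResult()
    for sp in sorted(per_species):
        total, acc, recs = min(per_species[sp], key=lambda t: (-t[0], t[1]))
        group = _make_group(sp, "single", _longest_per_locus(recs))
        result.chosen[sp] = (group, "plastome")
    return result
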