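"""Darwin Core taxonomy handling and scientific-name resolution.

Reference taxonomies for ferns (and most plant groups) are distributed as
Darwin Core tables: one row per name with ``taxonID``, ``scientificName``,
``taxonomicStatus`` (accepted/synonym), ``acceptedNameUsageID`` linking a
synonym to its accepted name, and ``parentNameUsageID`` linking each taxon
to its parent rank.  Names arriving from sequence repositories rarely match
such a reference verbatim: authorship may be formatted differently
(parenthetical basionym author present or absent), names may be misspelled,
and many are synonyms.  This module parses raw name strings, validates a
reference taxonomy, and resolves queries against it with exact-then-fuzzy
matching.

Matching strategy
-----------------
1. exact match on canonical name + authorship;
2. exact match on the canonical (authorless) name;
3. fuzzy match by Levenshtein distance over canonical names, bounded by
   ``max_distance`` (default scales with name length).

Candidates at equal canonical distance are ranked by normalized author
similarity; if that still ties, the match is reported *ambiguous* rather
than auto-resolved.  A trinomial is never fuzzily matched against a
binomial (and vice versa): rank-collapsing matches are false positives.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import edlib
import pandas as pd

__all__ = [
    "TaxonRecord",
    "ParsedName",
    "NameMatch",
    "Lineage",
    "Violation",
    "Taxonomy",
    "NameParseError",
    "ResolutionError",
    "parse_scientific_name",
    "match_name",
    "resolve_accepted",
    "validate_taxonomy",
    "lineage_of",
    "read_taxonomy",
    "write_taxonomy",
    "write_violations",
]


class NameParseError(ValueError):
    """Raised when a raw name string has no recognizable genus token."""


class ResolutionError(ValueError):
    """Raised when a match cannot be resolved to an accepted name."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class TaxonRecord:
    """One Darwin Core taxon row."""

    taxon_id: str
    scientific_name: str  # canonical, without authorship
    authorship: str = ""
    rank: str = "species"
    status: str = "accepted"  # accepted | synonym
    accepted_id: str = ""  # empty for accepted records
    parent_id: str = ""


@dataclass(frozen=True)
class ParsedName:
    genus: str
    epithet: str = ""
    infraspecific_rank: Optional[str] = None
    infraspecific_epithet: Optional[str] = None
    authorship: str = ""
    has_basionym_author: bool = False
    is_hybrid_formula: bool = False
    annotation: str = "none"  # none | aff | cf | environmental

    @property
    def canonical(self) -> str:
        parts = [self.genus]
        if self.epithet:
            parts.append(self.epithet)
        if self.infraspecific_rank and self.infraspecific_epithet:
            parts += [self.infraspecific_rank, self.infraspecific_epithet]
        return " ".join(parts)

    @property
    def full(self) -> str:
        return f"{self.canonical} {self.authorship}".strip()


@dataclass(frozen=True)
class NameMatch:
    query: ParsedName
    matched_id: Optional[str]
    resolved_accepted_id: Optional[str]
    match_kind: str  # exact_full | exact_canonical | fuzzy | none | ambiguous
    distance: int = 0


@dataclass(frozen=True)
class Lineage:
    species_id: str
    genus: str
    family: str
    order: str
    suborder: Optional[str] = None
    is_monotypic_family: bool = False


@dataclass(frozen=True)
class Violation:
    taxon_id: str
    kind: str
    detail: str = ""


# ---------------------------------------------------------------------------
# Name parsing


_INFRA_MARKERS = {"var.", "subsp.", "ssp.", "fo.", "forma"}
_HYBRID_SIGNS = {"×", "x", "X"}


def _normalize_ws(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip()


def _is_capitalized_name(tok: str) -> bool:
    return bool(re.match(r"^×?[A-Z][a-zà-ÿ-]+$", tok))


def _looks_like_hybrid_formula(tokens: list[str]) -> bool:
    # A formula joins two names with a multiplication sign between binomials:
    # a standalone x/× with a capitalized name token on each side.
    for i, tok in enumerate(tokens):
        if tok in _HYBRID_SIGNS and 0 < i < len(tokens) - 1:
            left_cap = any(_is_capitalized_name(t) for t in tokens[:i])
            right_cap = any(_is_capitalized_name(t) for t in tokens[i + 1 :])
            right_lower = re.match(r"^[a-zà-ÿ-]+$", tokens[i + 1])
            # "Genus epithet × Genus epithet" or "Genus epithet × epithet"
            if left_cap and (right_cap or (right_lower and i >= 2)):
                return True
    return False


def parse_scientific_name(raw: str) -> ParsedName:
    """Split a raw scientific-name string into canonical parts and authorship.

    Detects ``aff.``/``cf.`` annotations, environmental-sample labels,
    hybrid formulas, infraspecific ranks, and parenthetical basionym
    authors.  Parsing is deterministic; strings with no capitalized genus
    token raise :class:`NameParseError`.
    """
    s = _normalize_ws(raw)
    if not s:
        raise NameParseError("empty name string")

    annotation = "none"
    if re.search(r"\benvironmental\b", s, flags=re.IGNORECASE):
        annotation = "environmental"
    tokens = s.split(" ")

    hybrid = _looks_like_hybrid_formula(tokens)

    # strip annotation markers (aff., cf.) wherever they appear
    kept: list[str] = []
    for tok in tokens:
        low = tok.lower().rstrip(".") + "."
        if low in ("aff.", "cf."):
            annotation = low[:-1] if annotation == "none" else annotation
            continue
        if tok.lower() in ("sp.", "sp", "spp.", "cf", "aff"):
            if tok.lower() in ("cf", "aff"):
                annotation = tok.lower() if annotation == "none" else annotation
            continue
        kept.append(tok)

    if not kept or not _is_capitalized_name(kept[0]):
        raise NameParseError(f"no capitalized genus token in {raw!r}")

    genus = kept[0]
    i = 1
    epithet = ""
    if i < len(kept) and re.match(r"^[a-zà-ÿ][a-zà-ÿ-]*$", kept[i]):
        epithet = kept[i]
        i += 1

    infra_rank = infra_epi = None
    if (
        i + 1 < len(kept)
        and (
            kept[i] in _INFRA_MARKERS
            or (kept[i] == "f." and re.match(r"^[a-zà-ÿ-]+$", kept[i + 1]))
        )
        and re.match(r"^[a-zà-ÿ-]+$", kept[i + 1])
    ):
        infra_rank, infra_epi = kept[i], kept[i + 1]
        i += 2

    authorship = " ".join(kept[i:])
    return ParsedName(
        genus=genus,
        epithet=epithet,
        infraspecific_rank=infra_rank,
        infraspecific_epithet=infra_epi,
        authorship=authorship,
        has_basionym_author=authorship.startswith("("),
        is_hybrid_formula=hybrid,
        annotation=annotation,
    )


# ---------------------------------------------------------------------------
# Taxonomy container


class Taxonomy:
    """An indexed set of :class:`TaxonRecord` rows."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self.records: list[TaxonRecord] = list(records)
        self.by_id: dict[str, TaxonRecord] = {}
        for r in self.records:
            # keep first on duplicate; validate_taxonomy reports the defect
            self.by_id.setdefault(r.taxon_id, r)
        self._by_canonical: dict[str, list[TaxonRecord]] = {}
        for r in self.records:
            self._by_canonical.setdefault(r.scientific_name, []).append(r)
        self._family_species_count: Optional[dict[str, int]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def records_by_canonical(self, canonical: str) -> list[TaxonRecord]:
        return list(self._by_canonical.get(canonical, []))

    def accepted_species(self) -> list[TaxonRecord]:
        return [r for r in self.records if r.status == "accepted" and r.rank == "species"]

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[TaxonRecord]:
        rec = self.by_id.get(taxon_id)
        seen = set()
        while rec is not None and rec.taxon_id not in seen:
            if rec.rank == rank:
                return rec
            seen.add(rec.taxon_id)
            rec = self.by_id.get(rec.parent_id) if rec.parent_id else None
        return None

    def family_species_counts(self) -> dict[str, int]:
        """Accepted-species count per family taxon_id (cached)."""
        if self._family_species_count is None:
            counts: dict[str, int] = {}
            for sp in self.accepted_species():
                fam = self.ancestor_at_rank(sp.taxon_id, "family")
                if fam is not None:
                    counts[fam.taxon_id] = counts.get(fam.taxon_id, 0) + 1
            self._family_species_count = counts
        return self._family_species_count

    def with_edits(
        self,
        add: Iterable[TaxonRecord] = (),
        modify: Iterable[TaxonRecord] = (),
    ) -> "Taxonomy":
        """Return an edited copy, validated; raises on any violation.

        Edits go through this transaction rather than in-place mutation so
        a taxonomy in use can never silently lose its invariants.
        """
        modified = {r.taxon_id: r for r in modify}
        new_records = [modified.get(r.taxon_id, r) for r in self.records]
        new_records.extend(add)
        tax = Taxonomy(new_records)
        violations = validate_taxonomy(tax)
        if violations:
            raise ValueError(
                "taxonomy edit rejected: "
                + "; ".join(f"{v.taxon_id}:{v.kind}" for v in violations)
            )
        return tax


# ---------------------------------------------------------------------------
# Validation


def validate_taxonomy(records: Iterable[TaxonRecord] | Taxonomy) -> list[Violation]:
    """Check Darwin Core referential invariants; violations are data, not errors.

    Reported kinds: ``duplicate_id``, ``dangling_accepted``, ``dangling_parent``,
    ``synonym_chain``, ``missing_accepted``, ``cycle``.
    """
    recs = list(records) if not isinstance(records, Taxonomy) else records.records
    out: list[Violation] = []
    seen: dict[str, int] = {}
    for r in recs:
        seen[r.taxon_id] = seen.get(r.taxon_id, 0) + 1
    for tid, n in seen.items():
        if n > 1:
            out.append(Violation(tid, "duplicate_id", f"{n} records share this id"))
    by_id = {r.taxon_id: r for r in recs}
    for r in recs:
        if r.status == "synonym":
            if not r.accepted_id:
                out.append(Violation(r.taxon_id, "missing_accepted", "synonym with empty acceptedNameUsageID"))
            elif r.accepted_id not in by_id:
                out.append(Violation(r.taxon_id, "dangling_accepted", r.accepted_id))
            elif by_id[r.accepted_id].status != "accepted":
                out.append(Violation(r.taxon_id, "synonym_chain", f"accepted_id {r.accepted_id} is itself a synonym"))
        if r.parent_id and r.parent_id not in by_id:
            out.append(Violation(r.taxon_id, "dangling_parent", r.parent_id))
    # parent cycles
    for r in recs:
        slow = r.taxon_id
        path = set()
        cur = r
        while cur is not None and cur.parent_id:
            if cur.parent_id in path or cur.parent_id == r.taxon_id:
                out.append(Violation(r.taxon_id, "cycle", f"parent chain revisits {cur.parent_id}"))
                break
            path.add(cur.taxon_id)
            cur = by_id.get(cur.parent_id)
    return out


# ---------------------------------------------------------------------------
# Matching


def _normalize_author(a: str) -> str:
    return re.sub(r"[^a-z0-9 ]", "", a.lower()).strip()


def _author_similarity(a: str, b: str) -> float:
    na, nb = _normalize_author(a), _normalize_author(b)
    if not na and not nb:
        return 1.0
    return difflib.SequenceMatcher(None, na, nb).ratio()


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def default_max_distance(canonical: str) -> int:
    """Length-scaled fuzzy budget: one edit per 10 characters, capped at 3."""
    return min(3, max(1, len(canonical) // 10))


def _n_parts(canonical: str) -> int:
    return len(canonical.split())


def match_name(
    query: ParsedName | str,
    taxonomy: Taxonomy,
    max_distance: Optional[int] = None,
) -> NameMatch:
    """Match a parsed name against a taxonomy: exact, then canonical, then fuzzy."""
    if isinstance(query, str):
        query = parse_scientific_name(query)
    if len(taxonomy) == 0:
        raise ValueError("cannot match against an empty taxonomy")
    canonical = query.canonical
    if max_distance is None:
        max_distance = default_max_distance(canonical)
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")

    def _resolve(rec: TaxonRecord) -> Optional[str]:
        if rec.status == "accepted":
            return rec.taxon_id
        acc = taxonomy.by_id.get(rec.accepted_id)
        return acc.taxon_id if acc is not None and acc.status == "accepted" else None

    # stage 1: exact canonical + authorship
    cands = taxonomy.records_by_canonical(canonical)
    if query.authorship:
        exact_full = [
            r for r in cands
            if _normalize_author(r.authorship) == _normalize_author(query.authorship)
        ]
        if len(exact_full) == 1:
            r = exact_full[0]
            return NameMatch(query, r.taxon_id, _resolve(r), "exact_full", 0)

    # stage 2: exact canonical
    if len(cands) >= 1:
        if len(cands) == 1:
            r = cands[0]
            return NameMatch(query, r.taxon_id, _resolve(r), "exact_canonical", 0)
        ranked = sorted(
            cands,
            key=lambda r: (-_author_similarity(r.authorship, query.authorship), r.taxon_id),
        )
        best = _author_similarity(ranked[0].authorship, query.authorship)
        second = _author_similarity(ranked[1].authorship, query.authorship)
        if best > second:
            r = ranked[0]
            return NameMatch(query, r.taxon_id, _resolve(r), "exact_canonical", 0)
        return NameMatch(query, None, None, "ambiguous", 0)

    # stage 3: fuzzy over canonical names of the same part count
    # (a trinomial never fuzzily matches a binomial)
    nparts = _n_parts(canonical)
    best_d = max_distance + 1
    best_recs: list[TaxonRecord] = []
    for name, recs in taxonomy._by_canonical.items():
        if _n_parts(name) != nparts:
            continue
        d = _levenshtein(canonical, name)
        if d < best_d:
            best_d, best_recs = d, list(recs)
        elif d == best_d:
            best_recs.extend(recs)
    if best_d > max_distance or not best_recs:
        return NameMatch(query, None, None, "none", 0)
    if len(best_recs) == 1:
        r = best_recs[0]
        return NameMatch(query, r.taxon_id, _resolve(r), "fuzzy", best_d)
    ranked = sorted(
        best_recs,
        key=lambda r: (-_author_similarity(r.authorship, query.authorship), r.taxon_id),
    )
    if _author_similarity(ranked[0].authorship, query.authorship) > _author_similarity(
        ranked[1].authorship, query.authorship
    ):
        r = ranked[0]
        return NameMatch(query, r.taxon_id, _resolve(r), "fuzzy", best_d)
    return NameMatch(query, None, None, "ambiguous", best_d)


def resolve_accepted(match: NameMatch, taxonomy: Taxonomy) -> str:
    """Return the accepted taxon_id for a match (one synonym hop at most)."""
    if match.match_kind in ("none", "ambiguous"):
        raise ResolutionError(match.match_kind, match.query.canonical)
    rec = taxonomy.by_id.get(match.matched_id or "")
    if rec is None:
        raise ResolutionError("unknown_id", str(match.matched_id))
    if rec.status == "accepted":
        return rec.taxon_id
    acc = taxonomy.by_id.get(rec.accepted_id)
    if acc is None or acc.status != "accepted":
        raise ResolutionError("broken_synonym", rec.taxon_id)
    return acc.taxon_id


# ---------------------------------------------------------------------------
# Lineage


def lineage_of(species_taxon_id: str, taxonomy: Taxonomy) -> Lineage:
    """Walk the parent chain of an accepted species up to order rank."""
    rec = taxonomy.by_id.get(species_taxon_id)
    if rec is None:
        raise KeyError(f"unknown taxon_id {species_taxon_id!r}")
    if rec.status != "accepted" or rec.rank != "species":
        raise ValueError(f"{species_taxon_id} is not an accepted species")
    names: dict[str, str] = {}
    fam_id = None
    cur = rec
    while True:
        if cur.rank in ("genus", "family", "suborder", "order"):
            names.setdefault(cur.rank, cur.scientific_name)
            if cur.rank == "family" and fam_id is None:
                fam_id = cur.taxon_id
        if cur.rank == "order":
            break
        if not cur.parent_id:
            raise ValueError(
                f"broken parent chain for {species_taxon_id}: "
                f"{cur.taxon_id} ({cur.rank}) has no parent before order"
            )
        nxt = taxonomy.by_id.get(cur.parent_id)
        if nxt is None:
            raise ValueError(
                f"broken parent chain for {species_taxon_id}: missing ancestor {cur.parent_id}"
            )
        cur = nxt
    for needed in ("genus", "family", "order"):
        if needed not in names:
            raise ValueError(f"no {needed}-rank ancestor for {species_taxon_id}")
    monotypic = False
    if fam_id is not None:
        monotypic = taxonomy.family_species_counts().get(fam_id, 0) == 1
    return Lineage(
        species_id=species_taxon_id,
        genus=names["genus"],
        family=names["family"],
        suborder=names.get("suborder"),
        order=names["order"],
        is_monotypic_family=monotypic,
    )


# ---------------------------------------------------------------------------
# Darwin Core I/O

_DWC_COLS = {
    "taxonID": "taxon_id",
    "scientificName": "scientific_name",
    "scientificNameAuthorship": "authorship",
    "taxonRank": "rank",
    "taxonomicStatus": "status",
    "acceptedNameUsageID": "accepted_id",
    "parentNameUsageID": "parent_id",
}


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a Darwin Core taxon table (TSV or CSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = {"taxonID", "scientificName", "taxonomicStatus"} - set(df.columns)
    if missing:
        raise ValueError(f"missing Darwin Core columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            TaxonRecord(
                taxon_id=d.get("taxonID", ""),
                scientific_name=d.get("scientificName", ""),
                authorship=d.get("scientificNameAuthorship", ""),
                rank=d.get("taxonRank", "species"),
                status=d.get("taxonomicStatus", "accepted"),
                accepted_id=d.get("acceptedNameUsageID", ""),
                parent_id=d.get("parentNameUsageID", ""),
            )
        )
    return Taxonomy(records)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    rows = [
        {
            "taxonID": r.taxon_id,
            "scientificName": r.scientific_name,
            "scientificNameAuthorship": r.authorship,
            "taxonRank": r.rank,
            "taxonomicStatus": r.status,
            "acceptedNameUsageID": r.accepted_id,
            "parentNameUsageID": r.parent_id,
        }
        for r in taxonomy
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_violations(violations: list[Violation], path: str | Path) -> None:
    pd.DataFrame(
        [{"taxon_id": v.taxon_id, "kind": v.kind, "detail": v.detail} for v in violations],
        columns=["taxon_id", "kind", "detail"],
    ).to_csv(path, sep="\t", index=False)
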