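"""Accession curation and baited locus extraction.

Sequence repositories mix everything from single-locus Sanger reads to whole
plastomes under inconsistent annotation, so target loci are recovered by a
*baited search*: candidate sequences are locally aligned against a reference
database of full-length representative sequences (one longest representative
per genus per locus) and the matching span is extracted.  This module also
carries the admissibility filter (environmental samples, ``aff.``/``cf.``
annotations and hybrid formulas are excluded), the empirical Sanger/plastome
split at 7,000 bp of source-accession length, and the packaged locus
registry.

The registry ships 79 plastid loci: 77 protein-coding genes plus the two
commonly sequenced intergenic spacers (trnL-trnF, rps4-trnS).  Seven of
them (atpA, atpB, matK, rbcL, rps4 and the two spacers) are the classic
PCR/Sanger loci and are flagged ``tier=both``.  The gene list is a
synthetic, representative standard plastid gene set, not a copy of any
published table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .taxonomy import NameParseError, parse_scientific_name

__all__ = [
    "LocusDefinition",
    "SequenceRecord",
    "ReferenceSet",
    "ExtractionHit",
    "ExtractionParams",
    "DEFAULT_LOCI",
    "SANGER_LOCI",
    "PLASTOME_LOCI",
    "SPACER_LOCI",
    "reverse_complement",
    "ungapped_length",
    "filter_admissible",
    "classify_tier",
    "build_reference_db",
    "extract_locus",
    "extract_from_hits",
    "normalize_voucher",
    "publication_key",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_hits",
    "write_hits",
    "read_genbank_minimal",
]


@dataclass(frozen=True)
class LocusDefinition:
    name: str
    category: str  # coding | spacer
    tier: str  # sanger | plastome | both


def _default_registry() -> tuple[LocusDefinition, ...]:
    sanger_genes = ["atpA", "atpB", "matK", "rbcL", "rps4"]
    plastome_only_genes = [
        "atpE", "atpF", "atpH", "atpI",
        "accD", "ccsA", "cemA", "chlB", "chlL", "chlN", "clpP",
        "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
        "ndhI", "ndhJ", "ndhK",
        "petA", "petB", "petD", "petG", "petL", "petN",
        "psaA", "psaB", "psaC", "psaI", "psaJ",
        "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
        "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT",
        "rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32",
        "rpl33", "rpl36",
        "rpoA", "rpoB", "rpoC1", "rpoC2",
        "rps2", "rps3", "rps7", "rps8", "rps11", "rps12", "rps14",
        "rps15", "rps18", "rps19",
        "ycf1", "ycf2",
    ]
    spacers = ["trnL-trnF", "rps4-trnS"]
    out = [LocusDefinition(n, "coding", "both") for n in sanger_genes]
    out += [LocusDefinition(n, "coding", "plastome") for n in plastome_only_genes]
    out += [LocusDefinition(n, "spacer", "both") for n in spacers]
    return tuple(out)


DEFAULT_LOCI: tuple[LocusDefinition, ...] = _default_registry()
SANGER_LOCI: tuple[str, ...] = tuple(l.name for l in DEFAULT_LOCI if l.tier in ("sanger", "both"))
PLASTOME_LOCI: tuple[str, ...] = tuple(l.name for l in DEFAULT_LOCI if l.tier in ("plastome", "both"))
SPACER_LOCI: tuple[str, ...] = tuple(l.name for l in DEFAULT_LOCI if l.category == "spacer")


@dataclass(frozen=True)
class SequenceRecord:
    """One locus from one source accession."""

    accession: str
    locus: str
    species_id: str
    raw_name: str
    seq: str
    voucher: Optional[str] = None
    publication: Optional[str] = None
    tier: str = "sanger"


@dataclass
class ReferenceSet:
    """Per-locus reference sequences: one ungapped representative per genus."""

    refs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # locus -> [(genus, sequence)], sorted by genus

    def for_locus(self, locus: str) -> list[tuple[str, str]]:
        return self.refs.get(locus, [])


@dataclass(frozen=True)
class ExtractionHit:
    query_id: str
    ref_id: str
    q_start: int  # 0-based half-open on the (plus-strand) query
    q_end: int
    strand: str  # + | -
    score: float
    identity: float


@dataclass(frozen=True)
class ExtractionParams:
    min_score: float = 50.0
    min_identity: float = 0.7


_COMPLEMENT = str.maketrans("ACGTNacgtn?-", "TGCANtgcan?-")

_MISSING = set("?Nn-")
_ALLOWED = set("ACGTNacgtn?-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ungapped_length(seq: str) -> int:
    """Number of non-missing bases; missing = {"?", "N", "-"} (case-insensitive)."""
    n = 0
    for i, c in enumerate(seq):
        if c not in _ALLOWED:
            raise ValueError(f"illegal character {c!r} at position {i}")
        if c not in _MISSING:
            n += 1
    return n


def filter_admissible(
    records: Iterable[SequenceRecord],
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Drop environmental samples, aff./cf. annotations and hybrid formulas.

    Returns (kept, dropped) where each dropped record carries a reason code
    from {aff, cf, environmental, hybrid_formula, unparseable}.
    """
    kept: list[SequenceRecord] = []
    dropped: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        try:
            parsed = parse_scientific_name(rec.raw_name)
        except NameParseError:
            dropped.append((rec, "unparseable"))
            continue
        if parsed.is_hybrid_formula:
            dropped.append((rec, "hybrid_formula"))
        elif parsed.annotation != "none":
            dropped.append((rec, parsed.annotation))
        else:
            kept.append(rec)
    return kept, dropped


SANGER_MAX_LEN = 7000  # bp; source accessions above this are whole-plastome


def classify_tier(source_accession_length: int) -> str:
    """Empirical Sanger/plastome split on source-accession length."""
    if source_accession_length < 1:
        raise ValueError("source accession length must be >= 1")
    return "sanger" if source_accession_length <= SANGER_MAX_LEN else "plastome"


def build_reference_db(records: Iterable[SequenceRecord], taxonomy) -> ReferenceSet:
    """Keep, per locus and genus, the single longest (ungapped) sequence.

    Ties on length break by lexicographic accession id so the result is
    deterministic. Records whose species cannot be placed in a genus are
    skipped.
    """
    from .taxonomy import lineage_of

    best: dict[tuple[str, str], tuple[int, str, str]] = {}
    skipped: list[str] = []
    for rec in records:
        try:
            genus = lineage_of(rec.species_id, taxonomy).genus
        except (KeyError, ValueError):
            skipped.append(rec.accession)
            continue
        ungapped = rec.seq.replace("-", "").replace("?", "")
        key = (rec.locus, genus)
        cand = (-ungapped_length(ungapped), rec.accession, ungapped)
        if key not in best or cand < best[key]:
            best[key] = cand
    out = ReferenceSet()
    for (locus, genus), (_, _, seq) in sorted(best.items()):
        out.refs.setdefault(locus, []).append((genus, seq))
    out.skipped = skipped  # type: ignore[attr-defined]
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _best_local(aligner, candidate: str, ref: str):
    """Best local alignment span of candidate vs ref: (score, identity, start, end)."""
    alns = aligner.align(candidate.upper(), ref.upper())
    if len(alns) == 0:
        return None
    al = alns[0]
    blocks = al.aligned[0]
    if len(blocks) == 0:
        return None
    start, end = int(blocks[0][0]), int(blocks[-1][1])
    counts = al.counts()
    ncols = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / ncols if ncols else 0.0
    return float(al.score), identity, start, end


def extract_locus(
    candidate_seq: str,
    references: Sequence[tuple[str, str]],
    params: ExtractionParams = ExtractionParams(),
    query_id: str = "query",
) -> Optional[tuple[ExtractionHit, str]]:
    """Baited extraction: best local alignment against each reference, both strands.

    Returns the aligned span of the candidate (reverse-complemented to the
    plus strand when the best hit is on the minus strand), or ``None`` when
    no reference reaches both ``min_score`` and ``min_identity``.  Absence
    of a significant match is a value, not an error.
    """
    if not candidate_seq:
        raise ValueError("empty candidate sequence")
    if not references:
        raise ValueError("no references for locus")
    aligner = _make_aligner()
    rc = reverse_complement(candidate_seq)
    best = None  # (score, identity, strand, start, end, ref_id) on oriented seq
    for genus, ref in references:
        for strand, seq in (("+", candidate_seq), ("-", rc)):
            res = _best_local(aligner, seq, ref)
            if res is None:
                continue
            score, identity, start, end = res
            key = (-score, 0 if strand == "+" else 1, genus)
            if best is None or key < best[0]:
                best = (key, score, identity, strand, start, end, genus)
    if best is None:
        return None
    _, score, identity, strand, start, end, genus = best
    if score < params.min_score or identity < params.min_identity:
        return None
    oriented = candidate_seq if strand == "+" else rc
    extracted = oriented[start:end]
    if strand == "-":
        # map the span back to original (plus-strand input) coordinates
        L = len(candidate_seq)
        q_start, q_end = L - end, L - start
    else:
        q_start, q_end = start, end
    hit = ExtractionHit(query_id, genus, q_start, q_end, strand, score, identity)
    return hit, extracted


def extract_from_hits(
    candidate_seq: str,
    hit_rows: pd.DataFrame,
    query_id: str = "query",
) -> Optional[tuple[ExtractionHit, str]]:
    """Span extraction from a precomputed tabular (outfmt-6 dialect) hit file.

    Takes the best row by (bitscore desc, subject id asc); coordinates in the
    file are 1-based inclusive; minus-strand hits are indicated by
    sstart > send and the extracted span is reverse-complemented.
    """
    rows = hit_rows[hit_rows["qseqid"] == query_id] if "qseqid" in hit_rows else hit_rows
    if len(rows) == 0:
        return None
    rows = rows.sort_values(["bitscore", "sseqid"], ascending=[False, True])
    r = rows.iloc[0]
    q_start, q_end = int(r["qstart"]) - 1, int(r["qend"])
    strand = "-" if int(r["sstart"]) > int(r["send"]) else "+"
    sub = candidate_seq[q_start:q_end]
    if strand == "-":
        sub = reverse_complement(sub)
    hit = ExtractionHit(
        query_id, str(r["sseqid"]), q_start, q_end, strand,
        float(r["bitscore"]), float(r["pident"]) / 100.0,
    )
    return hit, sub


# ---------------------------------------------------------------------------
# Voucher / publication normalization


def normalize_voucher(voucher: Optional[str]) -> Optional[str]:
    """Case-fold, collapse whitespace, strip punctuation; None stays None."""
    if voucher is None or not voucher.strip():
        return None
    v = re.sub(r"[^\w\s]", "", voucher.casefold())
    return re.sub(r"\s+", " ", v).strip() or None


def publication_key(first_author: Optional[str], year: Optional[str], title: Optional[str]) -> Optional[str]:
    """Stable citation key: normalized (first-author, year, title-hash)."""
    if not first_author and not title:
        return None
    author = re.sub(r"[^a-z]", "", (first_author or "").casefold())
    t = re.sub(r"[^a-z0-9]", "", (title or "").casefold())
    import hashlib

    thash = hashlib.sha1(t.encode()).hexdigest()[:8] if t else "notitle"
    return f"{author or 'anon'}_{year or 'nd'}_{thash}"


# ---------------------------------------------------------------------------
# I/O

_FASTA_WRAP = 80


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """FASTA with ids accession|locus|taxon_id, wrapped at 80 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}|{rec.locus}|{rec.species_id}\n")
            for i in range(0, len(rec.seq), _FASTA_WRAP):
                fh.write(rec.seq[i : i + _FASTA_WRAP] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


_META_COLS = ["accession", "raw_name", "voucher", "publication", "source_length"]


def write_metadata(rows: Iterable[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows), columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"accession": str, "raw_name": str})


_HIT_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=_HIT_COLS, header=None)


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=_HIT_COLS)


def read_genbank_minimal(path: str | Path) -> list[dict]:
    """Minimal GenBank flatfile reader for fixture records.

    Returns one dict per record with accession, organism, specimen voucher,
    first-reference title/authors, and the sequence.  Anything beyond these
    fields is ignored.
    """
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        voucher = None
        for feat in rec.features:
            if "specimen_voucher" in feat.qualifiers:
                voucher = feat.qualifiers["specimen_voucher"][0]
                break
        refs = rec.annotations.get("references", [])
        out.append(
            {
                "accession": rec.id,
                "organism": rec.annotations.get("organism", ""),
                "voucher": voucher,
                "title": refs[0].title if refs else "",
                "authors": refs[0].authors if refs else "",
                "seq": str(rec.seq),
            }
        )
    return out
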