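"""Deterministic synthetic input bundles with planted ground truth.

Offline testing of a repository-mining pipeline needs a complete toy input
set: a reference taxonomy (with planted synonyms and misspellings, a
monotypic family, and analogues of the rank-override groups), per-accession
sequence records with vouchers and publications, an all-by-all similarity
table, gene trees and a species tree, and fossil calibrations.  Everything
is a pure function of ``(seed, size parameters)``; the *manifest* carries
the expected outputs (planted rogues, the representative each species
should get, the constraint each node should carry) derived from the
planted truth and a literal transcription of the selection rules, so the
pipeline can be checked end to end without network access or external
tools.

Sequences are simulated down a species tree under a Jukes-Cantor-style
independent-sites process (branch lengths in expected substitutions per
site, per-locus rate multipliers, no indels except gap columns planted in
the spacer locus for trimmer tests).  Families are separated by long
branches so within-family similarity always dominates between-family
similarity; rogues are planted by copying a sequence from a different
family group, which makes their nearest neighbours foreign by
construction.  All names, sequences and fossils are invented.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .calibration import FossilCalibration, write_calibrations
from .harvest import SequenceRecord, write_fasta, write_metadata
from .taxonomy import TaxonRecord, Taxonomy, write_taxonomy

__all__ = ["FixtureBundle", "Manifest", "make_toy_dataset"]

_BASES = "ACGT"

_GENUS_STEMS = [
    "Also", "Brachy", "Cteno", "Drymo", "Eupho", "Fimbri",
    "Glapho", "Hemio", "Ixo", "Jalo", "Kalo", "Lopho",
]
_EPITHETS = [
    "albida", "bicolor", "cordata", "elegans", "falcata", "gracilis",
    "hirsuta", "incisa", "lanceolata", "mirabilis", "nitida", "obtusa",
    "pallida", "reflexa", "scandens", "tenuifolia", "undulata", "venosa",
]
_SANGER_ORDER = ["rbcL", "atpB", "rps4", "trnL-trnF", "atpA", "matK", "rps4-trnS"]
_LOCUS_LEN = {
    "rbcL": 500, "atpB": 450, "rps4": 400, "trnL-trnF": 360,
    "atpA": 420, "matK": 480, "rps4-trnS": 300,
}
_PLASTOME_EXTRA = ["psbA", "ndhF", "rpoB", "rpl2", "psaA", "petA"]
OUTGROUP_LABEL = "OUTGROUP"


# ---------------------------------------------------------------------------
# Small rooted tree structure for construction/simulation


class _N:
    __slots__ = ("label", "children", "blen")

    def __init__(self, label=None, children=None, blen=0.0):
        self.label = label
        self.children = children or []
        self.blen = blen

    def leaves(self):
        if not self.children:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self):
        return self._nwk() + ";"

    def _nwk(self):
        if not self.children:
            return f"{self.label}:{self.blen:g}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.blen:g}"


def _caterpillar(units: list[_N], internal_blen: float) -> _N:
    cur = units[0]
    for nxt in units[1:]:
        cur = _N(children=[cur, nxt], blen=internal_blen)
    return cur


def _jc_prob(branch_length: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def _mutate(seq: str, p: float, rng: random.Random) -> str:
    out = []
    for c in seq:
        if c in _BASES and rng.random() < p:
            out.append(rng.choice([b for b in _BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _simulate(node: _N, parent_seq: str, rate: float, rng: random.Random,
              sink: dict[str, str]) -> None:
    seq = _mutate(parent_seq, _jc_prob(node.blen * rate), rng)
    if not node.children:
        sink[node.label] = seq
    for c in node.children:
        _simulate(c, seq, rate, rng, sink)


def _ungapped(seq: str) -> int:
    return sum(1 for c in seq if c not in "?Nn-")


# ---------------------------------------------------------------------------
# Bundle and manifest


@dataclass
class Manifest:
    name_resolution: dict[str, str] = field(default_factory=dict)  # accession -> species_id
    expected_dropped: dict[str, str] = field(default_factory=dict)  # accession -> reason
    expected_rogues: set[str] = field(default_factory=set)
    planted_monophyly: dict[str, bool] = field(default_factory=dict)
    expected_sanger: dict[str, tuple] = field(default_factory=dict)
    # species -> (rule, ((locus, accession), ...))
    expected_plastome: dict[str, str] = field(default_factory=dict)  # species -> accession
    expected_constraints: dict[str, tuple] = field(default_factory=dict)
    # calibration id -> (min_age, sorted leafset tuple)
    expected_superseded: dict[str, str] = field(default_factory=dict)  # loser -> winner
    expected_unassignable: dict[str, str] = field(default_factory=dict)  # id -> reason

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, set):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(self.__dict__, default=enc, indent=1, sort_keys=True)


@dataclass
class FixtureBundle:
    taxonomy: Taxonomy
    records: list[SequenceRecord]
    source_length: dict[str, int]  # accession -> source-accession length
    hit_rows: pd.DataFrame  # query, subject, score, evalue
    gene_trees: dict[str, str]  # locus -> newick (accession tips)
    species_tree: str  # newick, species tips + OUTGROUP
    outgroup_label: str
    calibrations: list[FossilCalibration]
    euphyllophyte_anchors: Optional[tuple[str, str]]
    sanger_loci: list[str]
    manifest: Manifest

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        write_fasta(self.records, out / "records.fasta")
        write_metadata(
            (
                {
                    "accession": r.accession,
                    "raw_name": r.raw_name,
                    "voucher": r.voucher or "",
                    "publication": r.publication or "",
                    "source_length": self.source_length.get(r.accession, len(r.seq)),
                }
                for r in self.records
            ),
            out / "metadata.tsv",
        )
        self.hit_rows.to_csv(out / "hits.tsv", sep="\t", index=False)
        for locus, nwk in self.gene_trees.items():
            (out / f"{locus}.nwk").write_text(nwk + "\n")
        (out / "species_tree.nwk").write_text(self.species_tree + "\n")
        write_calibrations(self.calibrations, out / "calibrations.csv")
        (out / "manifest.json").write_text(self.manifest.to_json() + "\n")


# ---------------------------------------------------------------------------
# Literal transcription of the concatenation conditions and selection rules,
# used only to fill the manifest.  Kept deliberately plain.


def _oracle_groups(recs: list[SequenceRecord], monophyletic: bool):
    def longest_per_locus(rs):
        best = {}
        for r in rs:
            k = (-_ungapped(r.seq), r.accession)
            if r.locus not in best or k < best[r.locus][0]:
                best[r.locus] = (k, r)
        return {l: r for l, (_, r) in best.items()}

    def group(basis, per_locus):
        members = tuple(sorted((l, r.accession) for l, r in per_locus.items()))
        total = sum(_ungapped(r.seq) for r in per_locus.values())
        return (basis, members, total, "rbcL" in per_locus)

    cands = []
    if monophyletic:
        cands.append(group("monophyly", longest_per_locus(recs)))
    vouchers = {}
    for r in recs:
        if r.voucher:
            vouchers.setdefault(r.voucher, []).append(r)
    for v in sorted(vouchers):
        cands.append(group("voucher", longest_per_locus(vouchers[v])))
    pubs = {r.publication for r in recs}
    if len(pubs) == 1 and None not in pubs and "" not in pubs:
        cands.append(group("publication", longest_per_locus(recs)))
    accs = {}
    for r in recs:
        accs.setdefault(r.accession, []).append(r)
    for a in sorted(accs):
        cands.append(group("single", longest_per_locus(accs[a])))
    return cands


def _oracle_select(recs_by_species, monophyly, rbcL_len):
    def key(g):
        _, members, total, _ = g
        return (-total, -len(members), tuple(sorted({a for _, a in members})))

    out = {}
    for sp in sorted(recs_by_species):
        cands = _oracle_groups(recs_by_species[sp], monophyly.get(sp, False))
        s1 = [g for g in cands if g[3] and len(g[1]) >= 2]
        if s1:
            g = min(s1, key=key)
            out[sp] = ("S1", g[1])
            continue
        s2 = [g for g in cands if g[3]]
        if s2:
            g = min(s2, key=lambda g: (-rbcL_len[dict(g[1])["rbcL"]], key(g)))
            out[sp] = ("S2", g[1])
            continue
        g = min(cands, key=key)
        out[sp] = ("S3", g[1])
    return out


# ---------------------------------------------------------------------------


def make_toy_dataset(
    seed: int,
    n_families: int = 5,
    n_species_per_family: int = 4,
    n_loci: int = 4,
    rogue_rate: float = 0.1,
) -> FixtureBundle:
    """Generate a complete toy input bundle with planted expected outputs.

    Same arguments, byte-identical bundle.  ``rogue_rate`` is the target
    fraction of Sanger accessions replaced by cross-family copies; the
    realized number is capped by the slots where a planted rogue is
    guaranteed detectable (host group keeps at least two clean species,
    donor group has at least three accessions of the locus).
    """
    if n_families < 1 or n_species_per_family < 1:
        raise ValueError("sizes must be >= 1")
    if not 1 <= n_loci <= len(_SANGER_ORDER):
        raise ValueError(f"n_loci must be in 1..{len(_SANGER_ORDER)}")
    if not 0.0 <= rogue_rate < 1.0:
        raise ValueError("rogue_rate must be in [0, 1)")
    if n_families > len(_GENUS_STEMS):
        raise ValueError(f"n_families must be <= {len(_GENUS_STEMS)}")

    rng = random.Random(seed)
    loci = _SANGER_ORDER[:n_loci]
    spacers = [l for l in loci if l in ("trnL-trnF", "rps4-trnS")]

    # ---- taxonomy -------------------------------------------------------
    records: list[TaxonRecord] = []
    records.append(TaxonRecord("ORD1", "Polypodiales", rank="order"))
    records.append(TaxonRecord("ORD2", "Cyatheales", rank="order"))
    records.append(
        TaxonRecord("SUB1", "Saccolomatineae", rank="suborder", parent_id="ORD1")
    )

    families = []  # (fam_id, fam_name, genus, species_ids, role)
    species_name: dict[str, str] = {}
    species_genus: dict[str, str] = {}
    synonym_name_of: dict[str, str] = {}
    sid = 0
    for i in range(n_families):
        stem = _GENUS_STEMS[i]
        genus = stem + "pteris"
        fam_name = stem + "pteridaceae"
        fam_id = f"FAM{i}"
        if i == 0:
            role, parent, n_sp = "monotypic", "ORD1", 1
        elif i in (1, 2) and n_families >= 3:
            role, parent, n_sp = "cyatheales", "ORD2", min(2, n_species_per_family)
        elif i == 3:
            role, parent, n_sp = "saccolomatineae", "SUB1", n_species_per_family
        else:
            role, parent, n_sp = "plain", "ORD1", n_species_per_family
        records.append(TaxonRecord(fam_id, fam_name, rank="family", parent_id=parent))
        gen_id = f"GEN{i}"
        records.append(TaxonRecord(gen_id, genus, rank="genus", parent_id=fam_id))
        sp_ids = []
        for j in range(n_sp):
            epithet = _EPITHETS[(i * 7 + j) % len(_EPITHETS)]
            name = f"{genus} {epithet}"
            sp_id = f"SP{sid:03d}"
            sid += 1
            records.append(
                TaxonRecord(sp_id, name, authorship="Sm.", rank="species", parent_id=gen_id)
            )
            species_name[sp_id] = name
            species_genus[sp_id] = genus
            sp_ids.append(sp_id)
            if rng.random() < 0.3:  # planted synonym
                syn = f"{stem}ella {epithet}"
                records.append(
                    TaxonRecord(
                        f"SYN{sp_id}", syn, authorship="Hook.", rank="species",
                        status="synonym", accepted_id=sp_id, parent_id=gen_id,
                    )
                )
                synonym_name_of[sp_id] = syn
        families.append((fam_id, fam_name, genus, sp_ids, role))
    taxonomy = Taxonomy(records)

    # comparison group per family: cyatheales families share one group
    group_of_family = {}
    for fam_id, _, _, _, role in families:
        group_of_family[fam_id] = "CYA_GROUP" if role == "cyatheales" else fam_id
    fam_of_species = {
        sp: fam_id for fam_id, _, _, sp_ids, _ in families for sp in sp_ids
    }

    # ---- species tree ---------------------------------------------------
    fam_clades: list[tuple[str, _N]] = []
    for fam_id, _, _, sp_ids, role in families:
        tips = [_N(label=sp, blen=0.02) for sp in sp_ids]
        clade = tips[0] if len(tips) == 1 else _caterpillar(tips, 0.03)
        clade.blen = 0.3
        fam_clades.append((fam_id, clade))
    # the two cyatheales families form one clade
    ladder_units: list[_N] = []
    cya = [c for f, c in fam_clades if group_of_family[f] == "CYA_GROUP"]
    for f, c in fam_clades:
        if group_of_family[f] == "CYA_GROUP":
            if c is cya[0] and len(cya) > 1:
                joint = _N(children=cya, blen=0.2)
                ladder_units.append(joint)
            elif len(cya) == 1:
                ladder_units.append(c)
        else:
            ladder_units.append(c)
    ingroup = _caterpillar(ladder_units, 0.2)
    out_tip = _N(label=OUTGROUP_LABEL, blen=1.0)
    root = _N(children=[ingroup, out_tip])
    species_tree_newick = root.newick()

    # leafsets needed for calibration expectations: crown and stem of each clade
    def _stem_leafset(target: _N) -> frozenset:
        # leafset of the parent node of `target` within the trimmed ingroup
        def walk(node):
            for c in node.children:
                if c is target:
                    return frozenset(node.leaves()) - {OUTGROUP_LABEL}
                got = walk(c)
                if got is not None:
                    return got
            return None

        return walk(root)

    crown_leafset = {f: frozenset(c.leaves()) for f, c in fam_clades}
    stem_leafset = {f: _stem_leafset(c) for f, c in fam_clades}

    # ---- sequence simulation -------------------------------------------
    species_seq: dict[str, dict[str, str]] = {}  # locus -> species -> seq
    for locus in loci:
        L = _LOCUS_LEN[locus]
        rate = 1.2 if locus in spacers else 1.0
        root_seq = "".join(rng.choice(_BASES) for _ in range(L))
        sink: dict[str, str] = {}
        _simulate(root, root_seq, rate, rng, sink)
        sink.pop(OUTGROUP_LABEL, None)
        species_seq[locus] = sink

    # which family skips rbcL (exercises selection rule S3)
    no_rbcL_family = None
    if n_loci >= 2:
        plains = [f for f, _, _, _, role in families if role == "plain"]
        if plains:
            no_rbcL_family = plains[-1]

    # ---- accession layout ----------------------------------------------
    # per (species, locus): 1 or 2 accessions; spacer keeps full length with
    # planted gap columns; coding loci get distinct truncations
    all_species = [sp for _, _, _, sp_ids, _ in families for sp in sp_ids]
    acc_counter = 0

    def new_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"AC{acc_counter:04d}"

    spacer_gap_cols: dict[str, list[int]] = {
        locus: sorted(rng.sample(range(20, _LOCUS_LEN[locus] - 20), 3))
        for locus in spacers
    }

    # species-level joining pattern
    pattern_of: dict[str, str] = {}
    for sp in all_species:
        pattern_of[sp] = rng.choice(["voucher", "publication", "none", "none"])

    two_acc: dict[tuple[str, str], bool] = {}
    for sp in all_species:
        for locus in loci:
            if locus == "rbcL" and fam_of_species[sp] == no_rbcL_family:
                continue
            two_acc[(sp, locus)] = rng.random() < 0.35

    # planted non-monophyletic species: need 2 accessions in a locus that a
    # same-family neighbour also samples (the graft target)
    nonmono_locus: dict[str, str] = {}
    for fam_id, _, _, sp_ids, _ in families:
        if len(sp_ids) < 2:
            continue
        for sp in sp_ids:
            cand_loci = [
                l
                for l in loci
                if two_acc.get((sp, l))
                and any((s, l) in two_acc for s in sp_ids if s != sp)
            ]
            if cand_loci and rng.random() < 0.3:
                nonmono_locus[sp] = rng.choice(cand_loci)
    planted_monophyly = {sp: sp not in nonmono_locus for sp in all_species}

    seq_records: list[SequenceRecord] = []
    source_length: dict[str, int] = {}
    manifest = Manifest(planted_monophyly=dict(planted_monophyly))
    acc_of: dict[tuple[str, str], list[str]] = {}  # (species, locus) -> accessions

    def styled_name(sp: str, acc_index: int) -> str:
        name = species_name[sp]
        style = rng.random()
        if style < 0.15 and sp in synonym_name_of:
            return synonym_name_of[sp] + " Hook."
        if style < 0.3:
            genus, epithet = name.split()
            k = len(epithet) // 2
            bad = "x" if epithet[k] != "x" else "y"
            return f"{genus} {epithet[:k]}{bad}{epithet[k + 1:]}"
        if style < 0.5:
            return name + " Sm."
        if style < 0.6:
            return name + " (Hook.) Sm."
        return name

    for sp in all_species:
        pat = pattern_of[sp]
        voucher = None
        publication = None
        if pat == "voucher":
            voucher = f"Coll {rng.randint(100, 999)}"
        if pat == "publication":
            publication = f"author{rng.randint(1, 9)}_20{rng.randint(10, 22)}_ref"
        for locus in loci:
            if (sp, locus) not in two_acc:
                continue
            n_acc = 2 if two_acc[(sp, locus)] else 1
            for k in range(n_acc):
                acc = new_acc()
                acc_of.setdefault((sp, locus), []).append(acc)
                base = species_seq[locus][sp]
                seq = _mutate(base, 0.01, rng)
                if locus in spacers:
                    if rng.random() < 0.5:
                        cols = spacer_gap_cols[locus]
                        seq = "".join(
                            "-" if i in cols else c for i, c in enumerate(seq)
                        )
                else:
                    delta = rng.randrange(0, _LOCUS_LEN[locus] // 4) if k > 0 or rng.random() < 0.5 else 0
                    if delta:
                        seq = seq[: len(seq) - delta]
                v = voucher
                if v is not None and k == 1:
                    v = v.upper() + "."  # same specimen, sloppier formatting
                seq_records.append(
                    SequenceRecord(
                        accession=acc, locus=locus, species_id="",
                        raw_name=styled_name(sp, k), seq=seq,
                        voucher=v, publication=publication, tier="sanger",
                    )
                )
                source_length[acc] = len(seq)
                manifest.name_resolution[acc] = sp
    # one boundary accession length: exactly at the Sanger cutoff
    if seq_records:
        source_length[seq_records[0].accession] = 7000

    # ---- inadmissible extras -------------------------------------------
    g0 = families[0][2]
    extras = [
        ("BAD1", f"{g0} cf. {_EPITHETS[0]}", "cf"),
        ("BAD2", f"{g0} aff. {_EPITHETS[1]}", "aff"),
        ("BAD3", f"{g0} {_EPITHETS[0]} × {g0} {_EPITHETS[1]}", "hybrid_formula"),
        ("BAD4", f"{g0} environmental sample", "environmental"),
    ]
    for acc, raw, reason in extras:
        seq_records.append(
            SequenceRecord(
                accession=acc, locus=loci[0], species_id="", raw_name=raw,
                seq="".join(rng.choice(_BASES) for _ in range(200)), tier="sanger",
            )
        )
        source_length[acc] = 200
        manifest.expected_dropped[acc] = reason

    # ---- rogues ---------------------------------------------------------
    sanger_accs = [r for r in seq_records if r.accession not in manifest.expected_dropped]
    group_species: dict[str, list[str]] = {}
    for fam_id, _, _, sp_ids, _ in families:
        group_species.setdefault(group_of_family[fam_id], []).extend(sp_ids)

    def group_of_sp(sp: str) -> str:
        return group_of_family[fam_of_species[sp]]

    # eligible host slots: single-accession (species, locus) in groups that
    # keep >=2 clean species sampling that locus after the plant; a (group,
    # locus) pair hosts at most one rogue and never doubles as a donor, so
    # every planted rogue stays unambiguously detectable
    eligible: list[tuple[str, str]] = []  # (species, locus)
    host_used: set[tuple[str, str]] = set()
    donor_used: set[tuple[str, str]] = set()
    nonmono_fam_locus = {
        (fam_of_species[sp], l) for sp, l in nonmono_locus.items()
    }
    for (sp, locus), accs in sorted(acc_of.items()):
        if len(accs) != 1:
            continue
        if (fam_of_species[sp], locus) in nonmono_fam_locus:
            continue  # keep graft neighbours of planted non-monophyly intact
        g = group_of_sp(sp)
        if len(group_species[g]) < 3:
            continue
        mates = [
            s for s in group_species[g] if s != sp and (s, locus) in acc_of
        ]
        if len(mates) >= 2:
            eligible.append((sp, locus))
    n_rogues = min(int(round(rogue_rate * len(sanger_accs))), len(eligible))
    rng.shuffle(eligible)
    planted_rogues: set[str] = set()
    for sp, locus in eligible:
        if len(planted_rogues) >= n_rogues:
            break
        g = group_of_sp(sp)
        if (g, locus) in host_used or (g, locus) in donor_used:
            continue
        donors = [
            d
            for d in sorted(group_species)
            if d != g
            and (d, locus) not in host_used
            and sum(len(acc_of.get((s, locus), [])) for s in group_species[d]) >= 3
        ]
        if not donors:
            continue
        donor_group = rng.choice(donors)
        donor_sp = rng.choice(
            [s for s in group_species[donor_group] if (s, locus) in acc_of]
        )
        acc = acc_of[(sp, locus)][0]
        rogue_seq = _mutate(species_seq[locus][donor_sp], 0.01, rng)
        for i, rec in enumerate(seq_records):
            if rec.accession == acc and rec.locus == locus:
                seq_records[i] = SequenceRecord(
                    accession=acc, locus=locus, species_id="",
                    raw_name=rec.raw_name, seq=rogue_seq,
                    voucher=rec.voucher, publication=rec.publication, tier="sanger",
                )
                break
        host_used.add((g, locus))
        donor_used.add((donor_group, locus))
        planted_rogues.add(acc)
    manifest.expected_rogues = planted_rogues

    # ---- plastome records ----------------------------------------------
    plastome_species: list[str] = []
    for fam_id, _, _, sp_ids, role in families:
        if role in ("saccolomatineae", "plain") and sp_ids:
            plastome_species.append(sp_ids[0])
        if len(plastome_species) == 2:
            break
    pl_counter = 0
    for idx, sp in enumerate(plastome_species):
        totals = {}
        for spec in range(2):
            pl_counter += 1
            acc = f"PL{pl_counter:03d}"
            total = 0
            for j, locus in enumerate(_PLASTOME_EXTRA):
                L = 300 + 10 * j + (20 if spec == idx % 2 else 0)
                seq = "".join(rng.choice(_BASES) for _ in range(L))
                total += L
                seq_records.append(
                    SequenceRecord(
                        accession=acc, locus=locus, species_id="",
                        raw_name=species_name[sp], seq=seq, tier="plastome",
                    )
                )
            source_length[acc] = 150000
            manifest.name_resolution[acc] = sp
            totals[acc] = total
        manifest.expected_plastome[sp] = max(totals, key=lambda a: (totals[a], a))

    # ---- all-by-all hit table (Sanger, admissible records only) --------
    from .harvest import _make_aligner

    aligner = _make_aligner()
    hit_entries = []
    for locus in loci:
        recs = [
            r
            for r in seq_records
            if r.locus == locus
            and r.tier == "sanger"
            and r.accession not in manifest.expected_dropped
        ]
        clean = {r.accession: r.seq.replace("-", "").replace("?", "") for r in recs}
        accs = sorted(clean)
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                score = float(aligner.score(clean[a], clean[b]))
                hit_entries.append((a, b, score, 0.0))
                hit_entries.append((b, a, score, 0.0))
    hit_rows = pd.DataFrame(hit_entries, columns=["query", "subject", "score", "evalue"])

    # ---- gene trees over clean accessions ------------------------------
    gene_trees: dict[str, str] = {}
    for locus in loci:
        fam_units = []
        for fam_id, _, _, sp_ids, _ in families:
            units: dict[str, _N] = {}
            grafts: list[tuple[str, str]] = []  # (host_sp, accession to graft)
            for sp in sp_ids:
                accs = [
                    a
                    for a in acc_of.get((sp, locus), [])
                    if a not in planted_rogues
                ]
                if not accs:
                    continue
                if sp in nonmono_locus and nonmono_locus[sp] == locus and len(accs) == 2:
                    units[sp] = _N(label=accs[0], blen=0.01)
                    grafts.append((sp, accs[1]))
                elif len(accs) == 1:
                    units[sp] = _N(label=accs[0], blen=0.01)
                else:
                    units[sp] = _N(
                        children=[_N(label=a, blen=0.005) for a in accs], blen=0.01
                    )
            for origin_sp, acc in grafts:
                hosts = [s for s in sp_ids if s != origin_sp and s in units]
                # planting guaranteed a sampled neighbour exists
                host = hosts[0]
                units[host] = _N(
                    children=[units[host], _N(label=acc, blen=0.005)], blen=0.01
                )
            ordered = [units[k] for k in sorted(units)]
            if not ordered:
                continue
            clade = ordered[0] if len(ordered) == 1 else _caterpillar(ordered, 0.02)
            clade.blen = 0.1
            fam_units.append(clade)
        if fam_units:
            tree = fam_units[0] if len(fam_units) == 1 else _caterpillar(fam_units, 0.05)
            gene_trees[locus] = tree.newick()

    # ---- calibrations ---------------------------------------------------
    calibrations: list[FossilCalibration] = []
    ages = rng.sample(range(40, 160), len(families) + 4)
    age_i = 0
    node_assignments: dict[str, tuple[frozenset, float]] = {}  # id -> (leafset, age)
    for fam_id, fam_name, _, sp_ids, role in families:
        if len(sp_ids) >= 2:
            cid = f"CAL_crown_{fam_id}"
            age = float(ages[age_i]); age_i += 1
            calibrations.append(
                FossilCalibration(
                    cid, f"Fossilis {fam_id.lower()}", fam_name, "crown",
                    (sp_ids[0], sp_ids[-1]), age, "Jurassic", "synthetic",
                )
            )
            node_assignments[cid] = (crown_leafset[fam_id], age)
    # redundant pair on the crown of the first >=2-species family
    big_fams = [f for f, _, _, sp_ids, _ in families if len(sp_ids) >= 2]
    if big_fams:
        f = big_fams[0]
        sp_ids = next(s for ff, _, _, s, _ in families if ff == f)
        cid = f"CAL_crown_{f}_b"
        age = float(ages[age_i]); age_i += 1
        calibrations.append(
            FossilCalibration(
                cid, f"Fossilis duplex", "dup", "crown",
                (sp_ids[0], sp_ids[-1]), age, "Triassic", "synthetic",
            )
        )
        node_assignments[cid] = (crown_leafset[f], age)
    # stem calibration on the monotypic family (single-tip stem)
    mono_fams = [(f, s) for f, _, _, s, role in families if role == "monotypic"]
    if mono_fams:
        f, sp_ids = mono_fams[0]
        cid = f"CAL_stem_{f}"
        age = float(ages[age_i]); age_i += 1
        calibrations.append(
            FossilCalibration(
                cid, "Fossilis solus", f, "stem", (sp_ids[0],), age,
                "Permian", "synthetic",
            )
        )
        node_assignments[cid] = (stem_leafset[f], age)
    # stem calibration on a multi-species family
    multi = [f for f, _, _, s, role in families if role in ("saccolomatineae", "plain") and len(s) >= 2]
    if multi:
        f = multi[0]
        sp_ids = next(s for ff, _, _, s, _ in families if ff == f)
        cid = f"CAL_stem_{f}"
        age = float(ages[age_i]); age_i += 1
        calibrations.append(
            FossilCalibration(
                cid, "Fossilis caulis", f, "stem", (sp_ids[0], sp_ids[-1]), age,
                "Cretaceous", "synthetic",
            )
        )
        node_assignments[cid] = (stem_leafset[f], age)
    # unassignable: anchors absent from the tree
    calibrations.append(
        FossilCalibration(
            "CAL_missing", "Fossilis absens", "none", "crown",
            ("SPX_ABSENT_A", "SPX_ABSENT_B"), 99.0, "Devonian", "synthetic",
        )
    )
    manifest.expected_unassignable["CAL_missing"] = "missing_anchor"
    # unassignable: stem of the whole ingroup (root has no parent)
    first_sp = families[0][3][0]
    last_sp = families[-1][3][-1]
    calibrations.append(
        FossilCalibration(
            "CAL_rootstem", "Fossilis radix", "ingroup", "stem",
            (first_sp, last_sp), 123.0, "Silurian", "synthetic",
        )
    )
    manifest.expected_unassignable["CAL_rootstem"] = "stem_at_root"

    # expected kept constraints: per node, the oldest (ties by id)
    by_node: dict[frozenset, list[tuple[str, float]]] = {}
    for cid, (leafset, age) in node_assignments.items():
        by_node.setdefault(leafset, []).append((cid, age))
    for leafset, group in by_node.items():
        group.sort(key=lambda t: (-t[1], t[0]))
        winner, age = group[0]
        manifest.expected_constraints[winner] = (age, tuple(sorted(leafset)))
        for loser, _ in group[1:]:
            manifest.expected_superseded[loser] = winner

    # euphyllophyte-analogue backbone anchors: two species whose MRCA is an
    # internal node (its stem gets the backbone minimum)
    euphy = None
    if n_families >= 3:
        cy_sp = families[1][3]
        if families[0][3] and cy_sp:
            euphy = (families[0][3][0], cy_sp[0])

    # ---- expected representatives (literal-rule oracle) -----------------
    clean_sanger: dict[str, list[SequenceRecord]] = {}
    rbcL_len: dict[str, int] = {}
    for rec in seq_records:
        acc = rec.accession
        if acc in manifest.expected_dropped or acc in planted_rogues:
            continue
        if rec.tier != "sanger":
            continue
        sp = manifest.name_resolution[acc]
        if sp in manifest.expected_plastome:
            continue
        # normalized voucher, as the pipeline will see it
        v = rec.voucher
        if v:
            import re as _re

            v = _re.sub(r"\s+", " ", _re.sub(r"[^\w\s]", "", v.casefold())).strip()
        clean_sanger.setdefault(sp, []).append(
            SequenceRecord(
                acc, rec.locus, sp, rec.raw_name, rec.seq, v, rec.publication, "sanger"
            )
        )
        if rec.locus == "rbcL":
            rbcL_len[acc] = _ungapped(rec.seq)
    manifest.expected_sanger = _oracle_select(clean_sanger, planted_monophyly, rbcL_len)

    return FixtureBundle(
        taxonomy=taxonomy,
        records=seq_records,
        source_length=source_length,
        hit_rows=hit_rows,
        gene_trees=gene_trees,
        species_tree=species_tree_newick,
        outgroup_label=OUTGROUP_LABEL,
        calibrations=calibrations,
        euphyllophyte_anchors=euphy,
        sanger_loci=loci,
        manifest=manifest,
    )
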