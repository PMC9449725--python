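"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package
implementation: literal rule transcriptions, exhaustive enumerations, and
a plain dynamic-programming local aligner.  Trees are represented as
nested tuples so clade/split enumeration does not share code with the
package's tree handling.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Nested-tuple trees: ("a", ("b", "c")) is a rooted tree; leaves are strings.


def tuple_tree_leaves(t):
    if isinstance(t, str):
        return [t]
    out = []
    for c in t:
        out.extend(tuple_tree_leaves(c))
    return out


def tuple_tree_clades(t):
    """All clade leafsets of a rooted tuple tree (including leaves and root)."""
    clades = []

    def walk(node):
        if isinstance(node, str):
            clades.append(frozenset([node]))
            return frozenset([node])
        s = frozenset()
        for c in node:
            s |= walk(c)
        clades.append(s)
        return s

    walk(t)
    return clades


def tuple_tree_newick(t, blen=1.0):
    def fmt(node):
        if isinstance(node, str):
            return f"{node}:{blen}"
        return "(" + ",".join(fmt(c) for c in node) + f"):{blen}"

    return fmt(t) + ";"


def random_tuple_tree(rng, leaves):
    """Random binary topology over the given leaf labels."""
    nodes = list(leaves)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def is_clade_rooted(t, tips):
    """Exhaustive enumeration: does `tips` form a clade of the rooted tree?"""
    tips = frozenset(tips)
    if len(tips) <= 1 or tips == frozenset(tuple_tree_leaves(t)):
        return True
    return tips in tuple_tree_clades(t)


def is_split_unrooted(t, tips):
    """Does `tips` form one side of a split of the tree read as unrooted?"""
    all_tips = frozenset(tuple_tree_leaves(t))
    tips = frozenset(tips)
    if len(tips) <= 1 or tips == all_tips:
        return True
    clades = tuple_tree_clades(t)
    return tips in clades or (all_tips - tips) in clades


# ---------------------------------------------------------------------------
# Literal transcription of the rogue rule.


def rogue_oracle(rows, species_of, lineage_of_species, overrides):
    """Re-implements the top-three foreign-taxon rule, literally.

    rows: list of (query, subject, score, evalue).
    lineage_of_species: species -> dict with family/order/suborder names and
    is_monotypic_family.  Returns query -> status string.
    """
    out = {}
    queries = sorted({q for q, *_ in rows})
    for q in queries:
        sp = species_of.get(q)
        if sp is None:
            continue
        lin = lineage_of_species[sp]
        rank = "family"
        for name in (lin["order"], lin.get("suborder"), lin["family"]):
            if name and name in overrides:
                rank = overrides[name]
                break
        own = lin.get(rank) or lin["family"]
        if lin["is_monotypic_family"]:
            out[q] = "exempt_monotypic"
            continue
        per_subject = {}
        for qq, s, score, ev in rows:
            if qq != q or s == q:
                continue
            key = (-score, ev)
            if s not in per_subject or key < per_subject[s]:
                per_subject[s] = key
        ranked = sorted(
            (key[0], key[1], s)
            for s, key in per_subject.items()
            if species_of.get(s) is not None
        )
        top3 = ranked[:3]
        if len(top3) < 3:
            out[q] = "indeterminate"
            continue
        taxa = []
        for _, _, s in top3:
            slin = lineage_of_species[species_of[s]]
            taxa.append(slin.get(rank) or slin["family"])
        out[q] = "rogue" if all(t != own for t in taxa) else "clean"
    return out


# ---------------------------------------------------------------------------
# Literal transcription of the concatenation conditions and selection rules.


def _ungapped(seq_len_map, acc):
    return seq_len_map[acc]


def selection_oracle(accessions, monophyletic, rbcL="rbcL"):
    """accessions: list of dicts with accession, locus, length, voucher,
    publication.  Returns (rule, members) with members a sorted tuple of
    (locus, accession)."""

    def longest_per_locus(accs):
        best = {}
        for a in accs:
            k = (-a["length"], a["accession"])
            if a["locus"] not in best or k < best[a["locus"]][0]:
                best[a["locus"]] = (k, a)
        return {l: a for l, (_, a) in best.items()}

    def group(per_locus):
        members = tuple(sorted((l, a["accession"]) for l, a in per_locus.items()))
        total = sum(a["length"] for a in per_locus.values())
        return {"members": members, "total": total, "has_rbcL": rbcL in per_locus,
                "rbcL_len": per_locus[rbcL]["length"] if rbcL in per_locus else 0}

    candidates = []
    # condition 1: monophyletic species
    if monophyletic:
        candidates.append(group(longest_per_locus(accessions)))
    # condition 2: same voucher specimen
    vouchers = {}
    for a in accessions:
        if a.get("voucher"):
            vouchers.setdefault(a["voucher"], []).append(a)
    for v in sorted(vouchers):
        candidates.append(group(longest_per_locus(vouchers[v])))
    # condition 3: all accessions from only one publication
    pubs = {a.get("publication") for a in accessions}
    if len(pubs) == 1 and None not in pubs:
        candidates.append(group(longest_per_locus(accessions)))
    # unconcatenated accessions
    per_acc = {}
    for a in accessions:
        per_acc.setdefault(a["accession"], []).append(a)
    for acc in sorted(per_acc):
        candidates.append(group(longest_per_locus(per_acc[acc])))

    def tiekey(g):
        return (-g["total"], -len(g["members"]),
                tuple(sorted({a for _, a in g["members"]})))

    s1 = [g for g in candidates if g["has_rbcL"] and len(g["members"]) >= 2]
    if s1:
        g = min(s1, key=tiekey)
        return ("S1", g["members"])
    s2 = [g for g in candidates if g["has_rbcL"]]
    if s2:
        g = min(s2, key=lambda g: (-g["rbcL_len"], tiekey(g)))
        return ("S2", g["members"])
    g = min(candidates, key=tiekey)
    return ("S3", g["members"])


# ---------------------------------------------------------------------------
# Plain Smith-Waterman (match +1, mismatch -1, gap -2), full DP.

_CODE = {c: i for i, c in enumerate("ACGT")}


def encode(seq):
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)


@njit(cache=True)
def _sw_fill(a, b):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            v = H[i - 1, j - 1] + s
            if H[i - 1, j] - 2 > v:
                v = H[i - 1, j] - 2
            if H[i, j - 1] - 2 > v:
                v = H[i, j - 1] - 2
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    return H, best, bi, bj


def smith_waterman(a_str, b_str):
    """Best local alignment of a vs b: (score, a_start, a_end) 0-based half-open."""
    a, b = encode(a_str), encode(b_str)
    H, best, bi, bj = _sw_fill(a, b)
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        s = 1 if a[i - 1] == b[j - 1] else -1
        if H[i, j] == H[i - 1, j - 1] + s:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - 2:
            i -= 1
        else:
            j -= 1
    return int(best), i, bi
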