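import random

import dendropy
import pandas as pd
import pytest

from fernmatrix.harvest import SequenceRecord
from fernmatrix.qc import (
    HitTable,
    apply_curated_lists,
    detect_rogues,
    monophyly_report,
    tip_set_is_monophyletic,
)
from fernmatrix.taxonomy import lineage_of

from conftest import build_taxonomy
from _oracles import (
    is_clade_rooted,
    is_split_unrooted,
    random_tuple_tree,
    rogue_oracle,
    tuple_tree_newick,
)


def _hits(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "score", "evalue"])


@pytest.fixture
def screen_taxonomy():
    tax, ids = build_taxonomy(
        {
            "Famaceae": {"Ferna": ["Ferna alba", "Ferna nigra", "Ferna alta"]},
            "Gernaceae": {"Gerna": ["Gerna una", "Gerna dua", "Gerna tria"]},
            "Monoaceae": {"Mona": ["Mona sola"]},
            "Cyatheaceae@Cyatheales": {"Cya": ["Cya prima", "Cya secunda"]},
            "Dicksoniaceae@Cyatheales": {"Dick": ["Dick tertia", "Dick quarta"]},
            "Saccolomataceae@Saccolomatineae": {"Sacco": ["Sacco magna", "Sacco parva"]},
        }
    )
    return tax, ids


class TestDetectRogues:
    def test_same_family_top_hit_is_clean(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        sp = {f"Q{i}": s for i, s in enumerate(
            [ids["Ferna alba"], ids["Ferna nigra"], ids["Gerna una"],
             ids["Gerna dua"], ids["Gerna tria"]])}
        rows = _hits([
            ("Q0", "Q1", 500, 0.0),
            ("Q0", "Q2", 90, 0.0), ("Q0", "Q3", 80, 0.0), ("Q0", "Q4", 70, 0.0),
        ])
        rep = detect_rogues(HitTable(rows, sp), tax)
        assert rep.rows["Q0"].status == "clean"
        assert not rep.rows["Q0"].flagged

    def test_three_foreign_hits_flag_rogue(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        sp = {"Q0": ids["Ferna alba"], "S1": ids["Gerna una"],
              "S2": ids["Gerna dua"], "S3": ids["Gerna tria"]}
        rows = _hits([
            ("Q0", "S1", 400, 0.0), ("Q0", "S2", 390, 0.0), ("Q0", "S3", 380, 0.0),
        ])
        rep = detect_rogues(HitTable(rows, sp), tax)
        assert rep.rows["Q0"].status == "rogue"
        assert rep.rows["Q0"].flagged

    def test_monotypic_family_exempt(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        sp = {"Q0": ids["Mona sola"], "S1": ids["Gerna una"],
              "S2": ids["Gerna dua"], "S3": ids["Gerna tria"]}
        rows = _hits([
            ("Q0", "S1", 400, 0.0), ("Q0", "S2", 390, 0.0), ("Q0", "S3", 380, 0.0),
        ])
        rep = detect_rogues(HitTable(rows, sp), tax)
        assert rep.rows["Q0"].status == "exempt_monotypic"
        assert not rep.rows["Q0"].flagged

    def test_fewer_than_three_hits_indeterminate(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        sp = {"Q0": ids["Ferna alba"], "S1": ids["Gerna una"], "S2": ids["Gerna dua"]}
        rows = _hits([("Q0", "S1", 400, 0.0), ("Q0", "S2", 390, 0.0)])
        rep = detect_rogues(HitTable(rows, sp), tax)
        assert rep.rows["Q0"].status == "indeterminate"
        assert not rep.rows["Q0"].flagged

    def test_cyatheales_compared_at_order(self, screen_taxonomy):
        # two tree-fern families: foreign family, same order -> clean
        tax, ids = screen_taxonomy
        sp = {"Q0": ids["Cya prima"], "S1": ids["Dick tertia"],
              "S2": ids["Dick quarta"], "S3": ids["Cya secunda"]}
        rows = _hits([
            ("Q0", "S1", 400, 0.0), ("Q0", "S2", 390, 0.0), ("Q0", "S3", 380, 0.0),
        ])
        rep = detect_rogues(HitTable(rows, sp), tax)
        assert rep.rows["Q0"].comparison_rank == "order"
        assert rep.rows["Q0"].status == "clean"

    def test_subject_best_row_collapse_and_order_invariance(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        sp = {"Q0": ids["Ferna alba"], "M1": ids["Ferna nigra"],
              "S1": ids["Gerna una"], "S2": ids["Gerna dua"], "S3": ids["Gerna tria"]}
        base = [
            ("Q0", "M1", 100, 0.0), ("Q0", "M1", 500, 0.0),  # collapse to 500
            ("Q0", "S1", 400, 0.0), ("Q0", "S2", 390, 0.0), ("Q0", "S3", 380, 0.0),
        ]
        statuses = set()
        rng = random.Random(0)
        for _ in range(5):
            rows = base[:]
            rng.shuffle(rows)
            rep = detect_rogues(HitTable(_hits(rows), sp), tax)
            statuses.add(rep.rows["Q0"].status)
        assert statuses == {"clean"}  # M1's best row (500) tops the ranking

    def test_random_tables_against_brute_force_oracle(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        species = list(ids.values())
        lineages = {}
        for s in species:
            lin = lineage_of(s, tax)
            lineages[s] = {
                "family": lin.family, "order": lin.order, "suborder": lin.suborder,
                "is_monotypic_family": lin.is_monotypic_family,
            }
        overrides = {"Cyatheales": "order", "Saccolomatineae": "suborder"}
        rng = random.Random(42)
        for _ in range(40):
            accs = [f"A{i}" for i in range(rng.randint(4, 12))]
            sp_map = {a: rng.choice(species) for a in accs}
            rows = []
            for q in accs:
                for s in rng.sample(accs, rng.randint(0, len(accs) - 1)):
                    rows.append((q, s, rng.randint(0, 500), rng.random()))
            rep = detect_rogues(HitTable(_hits(rows), sp_map), tax)
            expected = rogue_oracle(rows, sp_map, lineages, overrides)
            got = {q: r.status for q, r in rep.rows.items()}
            assert got == expected

    def test_removing_rogue_rows_never_flags_stable_clean_query(self, screen_taxonomy):
        tax, ids = screen_taxonomy
        sp = {"Q0": ids["Ferna alba"], "M1": ids["Ferna nigra"], "R": ids["Gerna una"],
              "S2": ids["Gerna dua"], "S3": ids["Gerna tria"]}
        rows = [
            ("Q0", "M1", 500, 0.0), ("Q0", "S2", 90, 0.0), ("Q0", "S3", 80, 0.0),
            ("R", "S2", 400, 0.0), ("R", "S3", 390, 0.0), ("R", "M1", 380, 0.0),
        ]
        rep1 = detect_rogues(HitTable(_hits(rows), sp), tax)
        assert rep1.rows["Q0"].status == "clean"
        pruned = [r for r in rows if r[0] != "R" and r[1] != "R"]
        rep2 = detect_rogues(HitTable(_hits(pruned), sp), tax)
        assert rep2.rows["Q0"].status == "clean"


class TestMonophylyReport:
    def _tax(self):
        return build_taxonomy(
            {"Famaceae": {"Alpha": ["Alpha una", "Alpha dua"],
                          "Beta": ["Beta una", "Beta dua"]}}
        )

    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_separated_genera_monophyletic(self):
        tax, ids = self._tax()
        t = self._tree(
            f"(({ids['Alpha una']},{ids['Alpha dua']}),({ids['Beta una']},{ids['Beta dua']}));"
        )
        rep = monophyly_report(t, tax, ranks=("genus",))
        assert rep.status_of("Alpha") == "monophyletic"
        assert rep.status_of("Beta") == "monophyletic"

    def test_interleaved_genera_with_intruders(self):
        tax, ids = self._tax()
        a1, a2 = ids["Alpha una"], ids["Alpha dua"]
        b1, b2 = ids["Beta una"], ids["Beta dua"]
        rep = monophyly_report(
            self._tree(f"(({a1},{b1}),({a2},{b2}));"), tax, ranks=("genus",)
        )
        assert rep.status_of("Alpha") == "non_monophyletic"
        assert rep.status_of("Beta") == "non_monophyletic"
        assert rep.statuses["Alpha"].intruders == ("Beta",)
        assert rep.statuses["Beta"].intruders == ("Alpha",)

    def test_single_tip_taxon_is_monotypic(self):
        tax, ids = self._tax()
        t = self._tree(f"(({ids['Alpha una']},{ids['Beta una']}),{ids['Beta dua']});")
        rep = monophyly_report(t, tax, ranks=("genus",))
        assert rep.status_of("Alpha") == "monotypic"

    def test_unresolvable_tip_errors(self):
        tax, _ = self._tax()
        t = self._tree("(unknown1,unknown2);")
        with pytest.raises(ValueError, match="unknown1"):
            monophyly_report(t, tax)

    def test_agrees_with_exhaustive_enumeration_small_trees(self):
        rng = random.Random(7)
        for _ in range(60):
            n = rng.randint(3, 10)
            leaves = [f"t{i}" for i in range(n)]
            tt = random_tuple_tree(rng, leaves)
            tree = dendropy.Tree.get(data=tuple_tree_newick(tt), schema="newick")
            k = rng.randint(1, n)
            tips = set(rng.sample(leaves, k))
            assert tip_set_is_monophyletic(tree, tips, rooted=True) == is_clade_rooted(tt, tips)
            assert tip_set_is_monophyletic(tree, tips, rooted=False) == is_split_unrooted(tt, tips)


class TestCuratedLists:
    def _recs(self):
        return [
            SequenceRecord("X1", "rbcL", "S1", "", "ACGT"),
            SequenceRecord("X2", "rbcL", "S1", "", "ACGT"),
            SequenceRecord("X3", "atpB", "S1", "", "ACGT"),
        ]

    def test_exclusion_removes_with_reason(self):
        kept, dropped, preferred, _ = apply_curated_lists(self._recs(), exclude_list={"X1"})
        assert [r.accession for r in kept] == ["X2", "X3"]
        assert dropped[0][1] == "curated_rogue"

    def test_inclusion_marks_preferred(self):
        kept, _, preferred, _ = apply_curated_lists(self._recs(), include_list={"X2"})
        assert preferred == {"X2"}
        assert len(kept) == 3

    def test_exclude_beats_include_and_logs_conflict(self):
        kept, dropped, preferred, log = apply_curated_lists(
            self._recs(), exclude_list={"X1"}, include_list={"X1"}
        )
        assert [r.accession for r in dropped for r in [r[0]]] == ["X1"]
        assert preferred == set()
        assert any("conflict" in line for line in log)

    def test_unknown_id_warns_not_errors(self):
        kept, _, _, log = apply_curated_lists(self._recs(), exclude_list={"NOPE"})
        assert len(kept) == 3
        assert any("NOPE" in line for line in log)

    def test_preferred_overrides_selection_downstream(self):
        from fernmatrix.sampling import build_concat_groups, select_sanger_representative

        recs = [
            SequenceRecord("X2", "rbcL", "S1", "", "A" * 100),
            SequenceRecord("X3", "rbcL", "S1", "", "A" * 900),
        ]
        kept, _, preferred, _ = apply_curated_lists(recs, include_list={"X2"})
        groups = build_concat_groups(kept, {})
        sel = select_sanger_representative(groups, kept, curated_preferences=preferred)
        group, rule = sel.chosen["S1"]
        assert rule == "curated"
        assert group.accessions == ("X2",)  # shorter, but include-listed
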