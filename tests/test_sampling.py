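import itertools
import random

import dendropy
import pytest

from fernmatrix.harvest import SequenceRecord
from fernmatrix.sampling import (
    GeneTreeSet,
    build_concat_groups,
    classify_species_monophyly,
    select_plastome_representative,
    select_sanger_representative,
)

from _oracles import (
    is_split_unrooted,
    random_tuple_tree,
    selection_oracle,
    tuple_tree_newick,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestClassifySpeciesMonophyly:
    def test_single_accession_is_vacuously_monophyletic(self):
        gts = GeneTreeSet(
            {"rbcL": _tree("((a1,b1),c1);")},
            {"a1": "A", "b1": "B", "c1": "C"},
        )
        assert classify_species_monophyly(gts) == {"A": True, "B": True, "C": True}

    def test_split_species_is_non_monophyletic(self):
        # A's two accessions separated by b1 on a 6-tip tree
        gts = GeneTreeSet(
            {"rbcL": _tree("(((a1,b1),(a2,b2)),(c1,c2));")},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"},
        )
        got = classify_species_monophyly(gts)
        assert got == {"A": False, "B": False, "C": True}

    def test_clade_in_every_tree_is_monophyletic(self):
        trees = {
            "rbcL": _tree("(((a1,a2),b1),c1);"),
            "atpB": _tree("((b1,(a1,a2)),c1);"),
        }
        gts = GeneTreeSet(trees, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        assert classify_species_monophyly(gts)["A"] is True

    def test_one_bad_tree_overrides_good_trees(self):
        trees = {
            "rbcL": _tree("(((a1,a2),b1),c1);"),
            "atpB": _tree("(((a1,b1),a2),c1);"),
        }
        gts = GeneTreeSet(trees, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        assert classify_species_monophyly(gts)["A"] is False

    def test_agreement_with_split_enumeration_on_random_trees(self):
        rng = random.Random(11)
        for _ in range(50):
            n = rng.randint(4, 12)
            leaves = [f"x{i}" for i in range(n)]
            species = {l: f"SP{rng.randint(0, 3)}" for l in leaves}
            tt = random_tuple_tree(rng, leaves)
            gts = GeneTreeSet({"locus": _tree(tuple_tree_newick(tt))}, species)
            got = classify_species_monophyly(gts)
            for sp in set(species.values()):
                tips = {l for l, s in species.items() if s == sp}
                expected = len(tips) < 2 or is_split_unrooted(tt, tips)
                assert got[sp] == expected, (sp, tips, tt)


def _rec(acc, locus, sp="S1", length=100, voucher=None, pub=None):
    return SequenceRecord(acc, locus, sp, "", "A" * length, voucher, pub)


class TestBuildConcatGroups:
    def test_monophyly_group_takes_longest_per_locus(self):
        recs = [
            _rec("A1", "rbcL", length=1300),
            _rec("A2", "rbcL", length=1200),
            _rec("A3", "atpB", length=700),
        ]
        groups = build_concat_groups(recs, {"S1": True})
        mono = [g for g in groups if g.basis == "monophyly"]
        assert len(mono) == 1
        assert dict(mono[0].members) == {"rbcL": "A1", "atpB": "A3"}
        assert mono[0].total_len == 2000

    def test_shared_voucher_groups_across_loci(self):
        recs = [
            _rec("A1", "rbcL", voucher="smith 123"),
            _rec("A2", "atpB", voucher="smith 123"),
        ]
        groups = build_concat_groups(recs, {})
        voucher = [g for g in groups if g.basis == "voucher"]
        assert len(voucher) == 1
        assert dict(voucher[0].members) == {"rbcL": "A1", "atpB": "A2"}

    def test_no_condition_leaves_only_singles(self):
        recs = [
            _rec("A1", "rbcL", voucher="v1", pub="p1"),
            _rec("A2", "atpB", voucher="v2", pub="p2"),
        ]
        groups = build_concat_groups(recs, {"S1": False})
        bases = sorted(g.basis for g in groups)
        assert bases == ["single", "single", "voucher", "voucher"]
        multi = [g for g in groups if len(g.members) > 1]
        assert multi == []

    def test_publication_requires_all_accessions_share_one(self):
        recs = [
            _rec("A1", "rbcL", pub="p1"),
            _rec("A2", "atpB", pub="p1"),
            _rec("A3", "rps4", pub="p2"),
        ]
        assert not any(
            g.basis == "publication" for g in build_concat_groups(recs, {})
        )
        recs2 = [r for r in recs if r.publication == "p1"]
        pub = [g for g in build_concat_groups(recs2, {}) if g.basis == "publication"]
        assert len(pub) == 1 and len(pub[0].members) == 2

    def test_missing_fields_never_satisfy_conditions(self):
        recs = [_rec("A1", "rbcL"), _rec("A2", "atpB")]
        groups = build_concat_groups(recs, {})
        assert {g.basis for g in groups} == {"single"}

    def test_partition_property(self):
        # every accession appears in >=1 candidate; none twice within a group
        rng = random.Random(3)
        for _ in range(20):
            recs = [
                _rec(
                    f"A{i}", rng.choice(["rbcL", "atpB", "rps4"]),
                    length=rng.randint(50, 500),
                    voucher=rng.choice([None, "v1", "v2"]),
                    pub=rng.choice([None, "p1"]),
                )
                for i in range(rng.randint(1, 6))
            ]
            groups = build_concat_groups(recs, {"S1": rng.random() < 0.5})
            covered = {a for g in groups for a in g.accessions}
            assert covered == {r.accession for r in recs}
            for g in groups:
                loci = [l for l, _ in g.members]
                assert len(loci) == len(set(loci))


class TestSelectSangerRepresentative:
    def test_rule_s1_prefers_multilocus_with_rbcL(self):
        recs = [
            _rec("A1", "rbcL", length=1300, voucher="v1"),
            _rec("A2", "atpB", length=1100, voucher="v1"),
            _rec("A3", "rbcL", length=1400),
        ]
        groups = build_concat_groups(recs, {})
        sel = select_sanger_representative(groups, recs)
        group, rule = sel.chosen["S1"]
        assert rule == "S1"
        assert dict(group.members) == {"rbcL": "A1", "atpB": "A2"}

    def test_rule_s2_longest_rbcL_only(self):
        recs = [_rec("A1", "rbcL", length=1300), _rec("A2", "rbcL", length=1250)]
        sel = select_sanger_representative(build_concat_groups(recs, {}), recs)
        group, rule = sel.chosen["S1"]
        assert rule == "S2"
        assert group.accessions == ("A1",)

    def test_rule_s3_longest_total_without_rbcL(self):
        recs = [
            _rec("A1", "atpB", length=900),
            _rec("A2", "rps4", length=1100),
        ]
        sel = select_sanger_representative(build_concat_groups(recs, {}), recs)
        group, rule = sel.chosen["S1"]
        assert rule == "S3"
        assert group.accessions == ("A2",)

    def test_lengthening_chosen_rbcL_never_changes_selection(self):
        base = [
            _rec("A1", "rbcL", length=1000, voucher="v1"),
            _rec("A2", "atpB", length=500, voucher="v1"),
            _rec("A3", "rbcL", length=900),
        ]
        sel1 = select_sanger_representative(build_concat_groups(base, {}), base)
        chosen1 = sel1.chosen["S1"][0].members
        longer = [
            SequenceRecord(r.accession, r.locus, r.species_id, "", "A" * 1500,
                           r.voucher, r.publication)
            if r.accession == "A1" else r
            for r in base
        ]
        sel2 = select_sanger_representative(build_concat_groups(longer, {}), longer)
        assert sel2.chosen["S1"][0].members == chosen1

    def test_exhaustive_configurations_match_literal_oracle(self):
        # all configurations: <=3 accessions x 3 loci x monophyly x shared
        # voucher x shared publication x two length patterns
        loci = ["rbcL", "atpB", "rps4"]
        count = 0
        for n_acc in (1, 2, 3):
            for locus_combo in itertools.product(loci, repeat=n_acc):
                for mono, shared_v, shared_p, equal_len in itertools.product(
                    [True, False], repeat=4
                ):
                    lengths = [500] * n_acc if equal_len else [800 - 100 * i for i in range(n_acc)]
                    accs = []
                    recs = []
                    for i in range(n_acc):
                        voucher = "v1" if shared_v else f"v{i+1}"
                        pub = "p1" if shared_p else f"p{i+1}"
                        accs.append(
                            {"accession": f"A{i+1}", "locus": locus_combo[i],
                             "length": lengths[i], "voucher": voucher,
                             "publication": pub}
                        )
                        recs.append(
                            _rec(f"A{i+1}", locus_combo[i], length=lengths[i],
                                 voucher=voucher, pub=pub)
                        )
                    expected = selection_oracle(accs, mono)
                    sel = select_sanger_representative(
                        build_concat_groups(recs, {"S1": mono}), recs
                    )
                    group, rule = sel.chosen["S1"]
                    assert (rule, group.members) == expected, (locus_combo, mono, shared_v, shared_p, equal_len)
                    count += 1
        assert count == 39 * 16


class TestSelectPlastomeRepresentative:
    def _specimen(self, acc, sp, lengths):
        return [
            SequenceRecord(acc, f"loc{i}", sp, "", "A" * L, tier="plastome")
            for i, L in enumerate(lengths)
        ]

    def test_single_specimen_selected(self):
        recs = self._specimen("P1", "S1", [100, 200])
        sel = select_plastome_representative(recs)
        assert sel.chosen["S1"][0].accessions == ("P1",)
        assert sel.chosen["S1"][1] == "plastome"

    def test_longest_combined_wins(self):
        recs = self._specimen("P1", "S1", [30000, 40000]) + self._specimen(
            "P2", "S1", [34000, 40000]
        )
        sel = select_plastome_representative(recs)
        assert sel.chosen["S1"][0].accessions == ("P2",)

    def test_tie_breaks_lexicographically(self):
        recs = self._specimen("P2", "S1", [500, 500]) + self._specimen(
            "P1", "S1", [400, 600]
        )
        sel = select_plastome_representative(recs)
        assert sel.chosen["S1"][0].accessions == ("P1",)

    def test_one_representative_per_species(self):
        recs = (
            self._specimen("P1", "S1", [100]) + self._specimen("P2", "S1", [90])
            + self._specimen("P3", "S2", [80])
        )
        sel = select_plastome_representative(recs)
        assert sorted(sel.chosen) == ["S1", "S2"]
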