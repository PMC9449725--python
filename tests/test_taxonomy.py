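import re

import pytest

from fernmatrix.taxonomy import (
    NameParseError,
    ResolutionError,
    TaxonRecord,
    Taxonomy,
    lineage_of,
    match_name,
    parse_scientific_name,
    resolve_accepted,
    validate_taxonomy,
)

from conftest import build_taxonomy


class TestParseScientificName:
    @pytest.mark.parametrize(
        "raw,genus,epithet,author,basionym",
        [
            ("Asplenium nidus L.", "Asplenium", "nidus", "L.", False),
            ("Asplenium nidus (Hook.) C. Presl", "Asplenium", "nidus", "(Hook.) C. Presl", True),
            ("Pteris vittata", "Pteris", "vittata", "", False),
            ("Dryopteris filix-mas (L.) Schott", "Dryopteris", "filix-mas", "(L.) Schott", True),
        ],
    )
    def test_binomials(self, raw, genus, epithet, author, basionym):
        p = parse_scientific_name(raw)
        assert (p.genus, p.epithet, p.authorship) == (genus, epithet, author)
        assert p.has_basionym_author is basionym
        assert not p.is_hybrid_formula and p.annotation == "none"

    def test_infraspecific(self):
        p = parse_scientific_name("Asplenium nidus var. major Sm.")
        assert p.infraspecific_rank == "var."
        assert p.infraspecific_epithet == "major"
        assert p.canonical == "Asplenium nidus var. major"
        assert p.authorship == "Sm."

    def test_hybrid_formula_flagged(self):
        p = parse_scientific_name("Equisetum arvense × Equisetum fluviatile")
        assert p.is_hybrid_formula

    def test_annotation_tokens_against_regex_oracle(self):
        # 50 constructed names; oracle = plain regex over annotation tokens
        genera = ["Amauropelta", "Pteris", "Cyathea", "Asplenium", "Adiantum"]
        epithets = ["rudis", "vittata", "nidus", "major", "minor"]
        styles = [
            "{g} {e}", "{g} sp. aff. {e}", "{g} cf. {e}", "{g} aff. {e}",
            "{g} {e} L.",
        ]
        names = [
            s.format(g=g, e=e)
            for g, e in zip(genera * 5, epithets * 5)
            for s in styles
        ][:50]
        for name in names:
            expected = "none"
            if re.search(r"\baff\.", name):
                expected = "aff"
            elif re.search(r"\bcf\.", name):
                expected = "cf"
            assert parse_scientific_name(name).annotation == expected, name

    def test_environmental_label(self):
        assert parse_scientific_name("Pteris environmental sample").annotation == "environmental"

    @pytest.mark.parametrize("raw", ["", "   ", "vittata minor"])
    def test_unparseable_raises(self, raw):
        with pytest.raises(NameParseError):
            parse_scientific_name(raw)


class TestMatchName:
    def test_exact_full_match(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        m = match_name("Pteris vittata Sm.", tax)
        assert m.match_kind == "exact_full"
        assert m.distance == 0
        assert m.resolved_accepted_id == ids["Pteris vittata"]

    def test_exact_canonical_ignores_author_formatting(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        m = match_name("Pteris vittata (Hook.) Sm.", tax)
        assert m.match_kind in ("exact_full", "exact_canonical")
        assert m.resolved_accepted_id == ids["Pteris vittata"]

    def test_fuzzy_matches_misspelling_with_exhaustive_oracle(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        query = "Cyathea contaminens"  # one substitution off
        # oracle: exhaustive Levenshtein over every canonical name
        def lev(a, b):
            dp = list(range(len(b) + 1))
            for i, ca in enumerate(a, 1):
                prev, dp[0] = dp[0], i
                for j, cb in enumerate(b, 1):
                    prev, dp[j] = dp[j], min(
                        dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb)
                    )
            return dp[-1]

        dists = {r.scientific_name: lev(query, r.scientific_name) for r in tax}
        best = min(dists.values())
        winners = [n for n, d in dists.items() if d == best]
        assert winners == ["Cyathea contaminans"] and best == 1
        m = match_name(query, tax, max_distance=1)
        assert m.match_kind == "fuzzy" and m.distance == 1
        assert m.resolved_accepted_id == ids["Cyathea contaminans"]

    def test_equidistant_candidates_are_ambiguous(self):
        tax, _ = build_taxonomy(
            {"Famaceae": {"Ferna": ["Ferna alba", "Ferna alta"]}}
        )
        m = match_name("Ferna alia", tax, max_distance=1)  # 1 from both
        assert m.match_kind == "ambiguous"
        assert m.resolved_accepted_id is None

    def test_trinomial_never_fuzzily_matches_binomial(self):
        tax, _ = build_taxonomy({"Famaceae": {"Ferna": ["Ferna alba"]}})
        p = parse_scientific_name("Ferna alba var. alba")
        m = match_name(p, tax, max_distance=3)
        assert m.match_kind == "none"

    def test_no_match_beyond_distance(self, fern_taxonomy):
        tax, _ = fern_taxonomy
        m = match_name("Zyzzyva nonexistens", tax, max_distance=2)
        assert m.match_kind == "none"

    def test_empty_taxonomy_errors(self):
        with pytest.raises(ValueError):
            match_name("Pteris vittata", Taxonomy([]))

    def test_monotonicity_in_max_distance(self, fern_taxonomy):
        # raising max_distance never changes a distance-0 result
        tax, _ = fern_taxonomy
        for name in ("Pteris vittata", "Asplenium nidus", "Saccoloma inaequale"):
            base = match_name(name, tax, max_distance=0)
            assert base.distance == 0
            for d in (1, 2, 3):
                again = match_name(name, tax, max_distance=d)
                assert again.matched_id == base.matched_id
                assert again.distance == 0


class TestResolveAccepted:
    def test_accepted_is_fixed_point(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        m = match_name("Adiantum capillus", tax)
        assert resolve_accepted(m, tax) == ids["Adiantum capillus"]

    def test_synonym_resolves_one_hop(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        m = match_name("Neottopteris nidus", tax)
        assert m.match_kind in ("exact_full", "exact_canonical")
        assert resolve_accepted(m, tax) == ids["Asplenium nidus"]

    def test_all_stored_synonyms_reproduce_accepted_mapping(self, fern_taxonomy):
        # resolve(match(synonym)) == stored accepted_id, for every synonym
        tax, _ = fern_taxonomy
        for rec in tax:
            if rec.status != "synonym":
                continue
            m = match_name(rec.scientific_name + " " + rec.authorship, tax)
            assert resolve_accepted(m, tax) == rec.accepted_id

    def test_ambiguous_fails_with_reason(self):
        tax, _ = build_taxonomy({"Famaceae": {"Ferna": ["Ferna alba", "Ferna alta"]}})
        m = match_name("Ferna alia", tax, max_distance=1)
        with pytest.raises(ResolutionError) as exc:
            resolve_accepted(m, tax)
        assert exc.value.reason == "ambiguous"


class TestValidateTaxonomy:
    def test_clean_taxonomy_is_empty(self, fern_taxonomy):
        tax, _ = fern_taxonomy
        assert validate_taxonomy(tax) == []

    def test_synonym_chain_detected(self):
        records = [
            TaxonRecord("a", "A a", rank="species", status="accepted"),
            TaxonRecord("b", "B b", rank="species", status="synonym", accepted_id="c"),
            TaxonRecord("c", "C c", rank="species", status="synonym", accepted_id="a"),
        ]
        kinds = {v.kind for v in validate_taxonomy(records)}
        assert "synonym_chain" in kinds

    def test_duplicate_id_detected(self):
        records = [
            TaxonRecord("x", "A a", rank="species"),
            TaxonRecord("x", "B b", rank="species"),
        ]
        violations = validate_taxonomy(records)
        assert [v.kind for v in violations] == ["duplicate_id"]

    def test_dangling_pointers_detected(self):
        records = [
            TaxonRecord("a", "A a", rank="species", status="synonym", accepted_id="zz"),
            TaxonRecord("b", "B b", rank="species", parent_id="zz"),
        ]
        kinds = sorted(v.kind for v in validate_taxonomy(records))
        assert kinds == ["dangling_accepted", "dangling_parent"]

    def test_edit_transaction_rejects_invalid(self, fern_taxonomy):
        tax, _ = fern_taxonomy
        bad = TaxonRecord("new1", "New species", rank="species",
                          status="synonym", accepted_id="nowhere")
        with pytest.raises(ValueError):
            tax.with_edits(add=[bad])
        good = TaxonRecord("new1", "Pteris nova", rank="species", parent_id="ORD1")
        assert "new1" in tax.with_edits(add=[good]).by_id


class TestLineage:
    def test_full_chain_and_monotypic_flag(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        lin = lineage_of(ids["Solus unicus"], tax)
        assert lin.family == "Monotypicaceae"
        assert lin.order == "Polypodiales"
        assert lin.is_monotypic_family
        lin2 = lineage_of(ids["Pteris vittata"], tax)
        assert not lin2.is_monotypic_family  # 3 species in Pteridaceae

    def test_order_and_suborder_resolved(self, fern_taxonomy):
        tax, ids = fern_taxonomy
        lin = lineage_of(ids["Cyathea contaminans"], tax)
        assert lin.order == "Cyatheales"
        lin2 = lineage_of(ids["Saccoloma inaequale"], tax)
        assert lin2.suborder == "Saccolomatineae"

    def test_broken_chain_names_missing_ancestor(self):
        records = [
            TaxonRecord("g", "Ferna", rank="genus"),  # no parent to order
            TaxonRecord("s", "Ferna alba", rank="species", parent_id="g"),
        ]
        with pytest.raises(ValueError, match="parent"):
            lineage_of("s", Taxonomy(records))


def test_darwin_core_round_trip(tmp_path, fern_taxonomy):
    from fernmatrix.taxonomy import read_taxonomy, write_taxonomy

    tax, _ = fern_taxonomy
    path = tmp_path / "tax.tsv"
    write_taxonomy(tax, path)
    back = read_taxonomy(path)
    assert {r.taxon_id for r in back} == {r.taxon_id for r in tax}
    assert validate_taxonomy(back) == []
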