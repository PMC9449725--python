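import pytest

from fernmatrix.taxonomy import TaxonRecord, Taxonomy


def build_taxonomy(families, synonyms=()):
    """families: {family_name: {genus_name: [species names]}} plus optional
    structure markers: a family name ending in '@Cyatheales' goes under the
    Cyatheales order, '@Saccolomatineae' under that suborder; everything
    else under Polypodiales."""
    records = [
        TaxonRecord("ORD1", "Polypodiales", rank="order"),
        TaxonRecord("ORD2", "Cyatheales", rank="order"),
        TaxonRecord("SUB1", "Saccolomatineae", rank="suborder", parent_id="ORD1"),
    ]
    counter = 0
    ids = {}
    for fam, genera in families.items():
        name, _, marker = fam.partition("@")
        parent = {"Cyatheales": "ORD2", "Saccolomatineae": "SUB1"}.get(marker, "ORD1")
        fid = f"F{counter}"
        counter += 1
        records.append(TaxonRecord(fid, name, rank="family", parent_id=parent))
        for genus, species in genera.items():
            gid = f"G{counter}"
            counter += 1
            records.append(TaxonRecord(gid, genus, rank="genus", parent_id=fid))
            for sp in species:
                sid = f"S{counter}"
                counter += 1
                records.append(
                    TaxonRecord(sid, sp, authorship="Sm.", rank="species", parent_id=gid)
                )
                ids[sp] = sid
    for syn_name, accepted_name in synonyms:
        counter += 1
        records.append(
            TaxonRecord(
                f"Y{counter}", syn_name, authorship="Hook.", rank="species",
                status="synonym", accepted_id=ids[accepted_name],
                parent_id="ORD1",
            )
        )
    return Taxonomy(records), ids


@pytest.fixture
def fern_taxonomy():
    """A small taxonomy: two ordinary families, a monotypic family, the two
    rank-override groups, and two synonyms."""
    tax, ids = build_taxonomy(
        {
            "Pteridaceae": {"Pteris": ["Pteris vittata", "Pteris cretica"],
                            "Adiantum": ["Adiantum capillus"]},
            "Aspleniaceae": {"Asplenium": ["Asplenium nidus", "Asplenium trichomanes"]},
            "Monotypicaceae": {"Solus": ["Solus unicus"]},
            "Cyatheaceae@Cyatheales": {"Cyathea": ["Cyathea contaminans"]},
            "Dicksoniaceae@Cyatheales": {"Dicksonia": ["Dicksonia antarctica"]},
            "Saccolomataceae@Saccolomatineae": {"Saccoloma": ["Saccoloma inaequale"]},
        },
        synonyms=[
            ("Pteris oldname", "Pteris vittata"),
            ("Neottopteris nidus", "Asplenium nidus"),
        ],
    )
    return tax, ids


@pytest.fixture(scope="session")
def toy_bundle():
    from fernmatrix.fixtures import make_toy_dataset

    return make_toy_dataset(1)
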