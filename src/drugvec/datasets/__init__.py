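"""Packaged reference data.

Currently one fixture: the drug/gene memberships and drug-gene relations
of the KEGG ErbB signaling pathway (hsa04012) — 19 drugs, 84 genes and 34
interaction pairs, with readable drug and gene symbols.
"""

from importlib import resources

from ..relations import (PathwayCatalog, PathwayEntry, RelationSet,
                         load_pathways, load_relations, restrict_to_pathway)

__all__ = ["load_erbb_fixture", "erbb_catalog", "ERBB_PATHWAY_ID"]

ERBB_PATHWAY_ID = "hsa04012"


def _data_path(name: str):
    return resources.files(__name__) / "data" / name


def erbb_catalog() -> PathwayCatalog:
    """The ErbB pathway memberships as a one-entry pathway catalog."""
    with resources.as_file(_data_path("erbb_members.tsv")) as p:
        return load_pathways(p)


def load_erbb_fixture() -> tuple[RelationSet, PathwayEntry]:
    """Load the packaged ErbB pathway fixture.

    Returns the 34 drug-gene pairs as a :class:`RelationSet` whose
    universes are the pathway memberships (19 drugs, 84 genes), together
    with the catalog entry.
    """
    catalog = erbb_catalog()
    entry = catalog[ERBB_PATHWAY_ID]
    with resources.as_file(_data_path("erbb_relations.tsv")) as p:
        relations = load_relations(p, drug_universe=entry.drugs,
                                   gene_universe=entry.genes)
    return relations, entry
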