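"""Packaged study data: the two eriophyoid annotation tables, the arrangement
panel (ancestor, eriophyoids, screen taxa) and the comparison tree."""

from __future__ import annotations

from importlib import resources

from .annotation import GenomeTable, parse_gene_table
from .gene_order import GeneOrder, read_arrangements

PT = "P_taishanensis"
ES = "E_sabinae"
ANCESTOR = "ancestral_arthropod"
#: arrangements screened against when calling shared derived clusters
SCREEN_TAXA = ("Argasidae", "Trombidiformes_sp_A", "Trombidiformes_sp_B", "Sarcoptiformes_sp")

GENOME_LENGTHS = {PT: 13475, ES: 13531}


def _read(name: str) -> str:
    return resources.files("mitoarch").joinpath("data", name).read_text()


def data_path(name: str) -> str:
    """Filesystem path of a packaged data file."""
    return str(resources.files("mitoarch").joinpath("data", name))


def load_table(taxon: str) -> GenomeTable:
    """Annotation table of one of the two eriophyoid mites, with genome length."""
    fname = {PT: "pt_table.tsv", ES: "es_table.tsv"}[taxon]
    return parse_gene_table(_read(fname), dialect="tsv", taxon=taxon,
                            genome_length=GENOME_LENGTHS[taxon])


def load_tables() -> dict[str, GenomeTable]:
    return {t: load_table(t) for t in (PT, ES)}


def load_arrangements() -> dict[str, GeneOrder]:
    return read_arrangements(_read("arrangements.txt"))


def load_tree_newick() -> str:
    return _read("tree.nwk")
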