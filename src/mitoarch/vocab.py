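"""The 37-gene metazoan mitochondrial vocabulary and the invertebrate mt genetic code.

Gene names follow the common short convention: ``cox1-3``, ``cob``, ``nad1-6``/``nad4L``,
``atp6``/``atp8``, ``rrnS``/``rrnL`` and ``trnX`` for tRNAs, with the two leucine and two
serine tRNAs disambiguated as ``trnL1`` (CUN codons, anticodon TAG), ``trnL2`` (UUR, TAA),
``trnS1`` (AGN, TCT) and ``trnS2`` (UCN, TGA).  ``CR`` denotes the control region, which is
annotation metadata rather than a gene.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

PCGS = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNAS = ("rrnS", "rrnL")
TRNAS = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
)
GENES37 = PCGS + RRNAS + TRNAS
CR = "CR"

#: canonical anticodon (DNA alphabet, as annotated) for each tRNA family
FAMILY_ANTICODON = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC", "trnC": "GCA",
    "trnQ": "TTG", "trnE": "TTC", "trnG": "TCC", "trnH": "GTG", "trnI": "GAT",
    "trnL1": "TAG", "trnL2": "TAA", "trnK": "TTT", "trnM": "CAT", "trnF": "GAA",
    "trnP": "TGG", "trnS1": "TCT", "trnS2": "TGA", "trnT": "TGT", "trnW": "TCA",
    "trnY": "GTA", "trnV": "TAC",
}
ANTICODON_FAMILY = {v: k for k, v in FAMILY_ANTICODON.items()}

#: one-letter amino acid per tRNA family
FAMILY_AA = {
    "trnA": "A", "trnR": "R", "trnN": "N", "trnD": "D", "trnC": "C",
    "trnQ": "Q", "trnE": "E", "trnG": "G", "trnH": "H", "trnI": "I",
    "trnL1": "L", "trnL2": "L", "trnK": "K", "trnM": "M", "trnF": "F",
    "trnP": "P", "trnS1": "S", "trnS2": "S", "trnT": "T", "trnW": "W",
    "trnY": "Y", "trnV": "V",
}

#: NCBI translation table 5 (invertebrate mitochondrial)
INVERT_MITO = CodonTable.unambiguous_dna_by_id[5]

_CASEMAP = {g.lower(): g for g in GENES37}
_CASEMAP["cr"] = CR
_ALIASES = {
    "nad4l": "nad4L", "cytb": "cob", "16s": "rrnL", "12s": "rrnS",
    "rrnl": "rrnL", "rrns": "rrnS",
}


def feature_class(gene: str) -> str:
    if gene in PCGS:
        return "PCG"
    if gene in RRNAS:
        return "rRNA"
    if gene in TRNAS:
        return "tRNA"
    if gene == CR:
        return "CR"
    raise ValueError(f"unknown gene label {gene!r}; vocabulary: {', '.join(GENES37)}, CR")


def canonical_gene_name(name: str, anticodon: str | None = None) -> str:
    """Normalize a gene label to the canonical vocabulary.

    Bare ``trnL``/``trnS`` are disambiguated by anticodon (TAG/TAA for leucine,
    TCT/TGA for serine) when one is supplied.
    """
    raw = name.strip()
    low = raw.lower()
    if low in ("trnl", "trns"):
        if anticodon is None:
            raise ValueError(f"ambiguous label {raw!r}: anticodon needed to split L1/L2 or S1/S2")
        fam = ANTICODON_FAMILY.get(anticodon.upper().replace("U", "T"))
        if fam is None or fam[:4].lower() != low:
            raise ValueError(f"anticodon {anticodon!r} does not identify a {raw!r} paralog")
        return fam
    if low in _ALIASES:
        return _ALIASES[low]
    if low in _CASEMAP:
        return _CASEMAP[low]
    raise ValueError(f"unknown gene label {raw!r}; vocabulary: {', '.join(GENES37)}, CR")


def canonical_strand(strand: str) -> str:
    s = strand.strip()
    if s in ("J", "+"):
        return "J"
    if s in ("N", "-", "−"):
        return "N"
    raise ValueError(f"strand must be one of J/N/+/-, got {strand!r}")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_mito(seq: str) -> str:
    """Translate a DNA string with the invertebrate mitochondrial code (no stop trimming)."""
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate(table=5))
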