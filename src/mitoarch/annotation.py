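"""Per-genome annotation tables and the arithmetic derived from them.

The unit of input is an annotation table: one row per feature with 1-based
inclusive start/end coordinates on a circular genome, a strand (J = majority
reading strand, N = minority), and for tRNAs an anticodon.  From such a table
the module computes genome length, intergenic gaps/overlaps (including the
pair that wraps the origin), strand usage, start/stop codons (when a genome
sequence is available) and the circular signed gene order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import vocab
from .gene_order import GeneOrder, SignedGene

TSV_COLUMNS = ("gene", "class", "strand", "start", "end", "anticodon",
               "printed_gap", "start_codon", "stop_codon")


@dataclass(frozen=True)
class AnnotationRecord:
    gene_name: str
    feature_class: str          # PCG | rRNA | tRNA | CR
    strand: str | None          # J | N; None for CR
    start: int                  # 1-based inclusive
    end: int
    anticodon: str | None = None
    printed_gap: int | None = None   # intergenic count as printed in the source table
    start_codon: str | None = None   # codon identities as annotated (optional metadata)
    stop_codon: str | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.gene_name}: need 1 <= start <= end, got {self.start}..{self.end}")
        if self.feature_class == "tRNA":
            if self.anticodon is None:
                raise ValueError(f"{self.gene_name}: tRNA requires an anticodon")
            if not 40 <= self.length <= 100:
                raise ValueError(f"{self.gene_name}: tRNA length {self.length} outside [40, 100]")
        elif self.anticodon is not None:
            raise ValueError(f"{self.gene_name}: anticodon only valid for tRNAs")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeTable:
    """Coordinate-sorted annotation records of one circular genome."""

    taxon: str
    records: tuple[AnnotationRecord, ...]
    genome_length: int | None = None

    def __post_init__(self):
        names = [r.gene_name for r in self.records if r.feature_class != "CR"]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"{self.taxon}: duplicate gene name(s): {sorted(dup)}")
        if sum(r.feature_class == "CR" for r in self.records) > 1:
            raise ValueError(f"{self.taxon}: more than one control region")
        if self.genome_length is not None and self.records:
            if self.genome_length < max(r.end for r in self.records):
                raise ValueError(f"{self.taxon}: genome_length < max(end)")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> tuple[AnnotationRecord, ...]:
        return tuple(r for r in self.records if r.feature_class != "CR")

    @property
    def cr(self) -> AnnotationRecord | None:
        for r in self.records:
            if r.feature_class == "CR":
                return r
        return None

    def record(self, gene_name: str) -> AnnotationRecord:
        for r in self.records:
            if r.gene_name == gene_name:
                return r
        raise KeyError(gene_name)


@dataclass(frozen=True)
class GapReport:
    """Intergenic nucleotides between coordinate-adjacent features.

    One entry per adjacent pair, wrapping the origin; negative values are
    overlaps.  Feature lengths plus gaps tile the circle exactly:
    sum(lengths) + sum(gaps) == genome_length.
    """

    taxon: str
    entries: tuple[tuple[str, str, int], ...]  # (upstream, downstream, gap)

    def gap(self, upstream: str, downstream: str) -> int:
        for u, d, g in self.entries:
            if (u, d) == (upstream, downstream):
                return g
        raise KeyError((upstream, downstream))

    def max_gap(self, exclude_cr: bool = True) -> int:
        gaps = [g for u, d, g in self.entries
                if not (exclude_cr and "CR" in (u, d))]
        return max(gaps)


_SORT_KEY = lambda r: (r.start, r.end, r.gene_name)


def _sorted_records(records) -> tuple[AnnotationRecord, ...]:
    return tuple(sorted(records, key=_SORT_KEY))


def parse_gene_table(source: str, dialect: str = "tsv", taxon: str = "",
                     genome_length: int | None = None) -> GenomeTable:
    """Parse an annotation table (TSV or GenBank-like feature dialect).

    Records are returned coordinate-sorted (start, then end, then name),
    which for genomes such as *E. sabinae* differs from printed row order.
    """
    if not source or not source.strip():
        raise ValueError("empty annotation table")
    if dialect == "tsv":
        records = _parse_tsv(source)
    elif dialect == "genbank-feature":
        records = _parse_genbank_features(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return GenomeTable(taxon=taxon, records=_sorted_records(records),
                       genome_length=genome_length)


def _parse_tsv(text: str) -> list[AnnotationRecord]:
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    header = [h.strip() for h in lines[0].split("\t")]
    required = ("gene", "class", "strand", "start", "end")
    for col in required:
        if col not in header:
            raise ValueError(f"TSV header missing column {col!r} (have {header})")
    idx = {h: i for i, h in enumerate(header)}
    records = []
    for line in lines[1:]:
        cells = line.split("\t")

        def cell(col):
            i = idx.get(col)
            if i is None or i >= len(cells):
                return None
            v = cells[i].strip()
            return v if v not in ("", ".") else None

        anticodon = cell("anticodon")
        name = vocab.canonical_gene_name(cell("gene"), anticodon)
        fclass = vocab.feature_class(name)
        declared = cell("class")
        if declared and declared != fclass:
            raise ValueError(f"{name}: declared class {declared!r} != {fclass!r}")
        strand = None if fclass == "CR" else vocab.canonical_strand(cell("strand"))
        try:
            start, end = int(cell("start")), int(cell("end"))
        except (TypeError, ValueError):
            raise ValueError(f"{name}: start/end must be integers")
        pg = cell("printed_gap")
        records.append(AnnotationRecord(
            gene_name=name, feature_class=fclass, strand=strand, start=start, end=end,
            anticodon=anticodon if fclass == "tRNA" else None,
            printed_gap=int(pg) if pg is not None else None,
            start_codon=cell("start_codon"), stop_codon=cell("stop_codon")))
    return records


_FEAT_RE = re.compile(
    r"^\s{0,8}(gene|tRNA|rRNA|CDS|misc_feature|D-loop)\s+"
    r"(complement\()?(\d+)\.\.(\d+)\)?\s*$")
_QUAL_RE = re.compile(r'^\s+/(\w+)="?([^"]*)"?\s*$')


def _parse_genbank_features(text: str) -> list[AnnotationRecord]:
    """Parse a bare GenBank-style feature table (feature lines + qualifiers)."""
    feats: list[dict] = []
    for line in text.splitlines():
        m = _FEAT_RE.match(line)
        if m:
            kind, comp, a, b = m.group(1), m.group(2), int(m.group(3)), int(m.group(4))
            feats.append({"kind": kind, "strand": "N" if comp else "J",
                          "start": a, "end": b, "quals": {}})
            continue
        q = _QUAL_RE.match(line)
        if q and feats:
            feats[-1]["quals"][q.group(1)] = q.group(2)
    records = []
    for f in feats:
        if f["kind"] == "gene":  # gene features duplicate their CDS/tRNA partners
            continue
        quals = f["quals"]
        anticodon = quals.get("anticodon")
        if f["kind"] in ("misc_feature", "D-loop"):
            name, fclass, strand = "CR", "CR", None
        else:
            label = quals.get("gene") or quals.get("product")
            if label is None:
                raise ValueError(f"feature at {f['start']}..{f['end']} lacks a gene/product label")
            name = vocab.canonical_gene_name(label, anticodon)
            fclass = vocab.feature_class(name)
            strand = f["strand"]
        records.append(AnnotationRecord(
            gene_name=name, feature_class=fclass, strand=strand,
            start=f["start"], end=f["end"],
            anticodon=anticodon if fclass == "tRNA" else None))
    return records


def write_gene_table(table: GenomeTable) -> str:
    """Serialize to the TSV dialect (inverse of :func:`parse_gene_table`)."""
    lines = ["\t".join(TSV_COLUMNS)]
    for r in table.records:
        lines.append("\t".join([
            r.gene_name, r.feature_class, r.strand or ".",
            str(r.start), str(r.end), r.anticodon or ".",
            "." if r.printed_gap is None else str(r.printed_gap),
            r.start_codon or ".", r.stop_codon or "."]))
    return "\n".join(lines) + "\n"


def infer_genome_length(table: GenomeTable, declared_wrap_gap: int) -> int:
    """Close the circle from the table alone.

    ``declared_wrap_gap`` is the intergenic count printed for the first
    feature, i.e. the gap between the last feature (by coordinate) and the
    first across the origin: length = max(end) + wrap_gap - (first.start - 1).
    """
    if not table.records:
        raise ValueError("cannot infer length of an empty table")
    first = table.records[0]
    length = max(r.end for r in table.records) + declared_wrap_gap - (first.start - 1)
    if length <= 0:
        raise ValueError(f"inferred genome length {length} is not positive")
    return length


def intergenic_gaps(table: GenomeTable) -> GapReport:
    """Gap (negative: overlap) between each pair of coordinate-adjacent
    features, including the origin-wrapping pair."""
    if table.genome_length is None:
        raise ValueError("genome_length required to compute the wrap gap")
    recs = table.records
    entries = []
    for up, down in zip(recs, recs[1:]):
        entries.append((up.gene_name, down.gene_name, down.start - up.end - 1))
    last, first = recs[-1], recs[0]
    entries.append((last.gene_name, first.gene_name,
                    first.start + table.genome_length - last.end - 1))
    return GapReport(taxon=table.taxon, entries=tuple(entries))


def strand_counts(table: GenomeTable) -> tuple[int, int]:
    """(J, N) gene counts; the CR has no strand and is not counted."""
    j = sum(r.strand == "J" for r in table.genes)
    n = sum(r.strand == "N" for r in table.genes)
    return j, n


def gene_order_from_table(table: GenomeTable, include_cr: bool = True) -> GeneOrder:
    """The circular signed gene order implied by the coordinates.

    Orientation is + for J-strand genes and - for N-strand genes; overlapping
    features keep coordinate (start) order.
    """
    if not table.records:
        raise ValueError("empty table has no gene order")
    genes: list[SignedGene] = []
    cr_after = None
    for r in table.records:
        if r.feature_class == "CR":
            if include_cr:
                cr_after = genes[-1][0] if genes else "__pending__"
            continue
        genes.append((r.gene_name, 1 if r.strand == "J" else -1))
    if cr_after == "__pending__":  # CR is the first feature: it follows the last gene
        cr_after = genes[-1][0]
    return GeneOrder(taxon=table.taxon, genes=tuple(genes), cr_after=cr_after)


@dataclass(frozen=True)
class CodonReport:
    gene: str
    start_codon: str
    stop_codon: str
    complete: bool
    internal_stops: tuple[int, ...] = ()   # codon indices; reported, not fatal


def extract_codons(genome_seq: str, table: GenomeTable) -> dict[str, CodonReport]:
    """Start/stop codons of every protein-coding gene.

    N-strand genes are reverse-complemented before reading.  A trailing T or
    TA (gene length not a codon multiple) is an incomplete stop, completed to
    TAA by post-transcriptional polyadenylation.  In-frame internal stops are
    reported as warnings, not errors.
    """
    seq = genome_seq.upper().replace("U", "T")
    out = {}
    for r in table.records:
        if r.feature_class != "PCG":
            continue
        if r.end > len(seq):
            raise ValueError(f"{r.gene_name}: coordinates exceed sequence length {len(seq)}")
        sub = seq[r.start - 1:r.end]
        if r.strand == "N":
            sub = vocab.revcomp(sub)
        rem = len(sub) % 3
        if rem:
            stop, complete = sub[-rem:], False
        else:
            stop, complete = sub[-3:], True
        n_codons = (len(sub) - rem) // 3
        coding = sub[:3 * (n_codons - (1 if complete else 0))]
        aa = vocab.translate_mito(coding)
        internal = tuple(i for i, c in enumerate(aa) if c == "*")
        out[r.gene_name] = CodonReport(
            gene=r.gene_name, start_codon=sub[:3], stop_codon=stop,
            complete=complete, internal_stops=internal)
    return out


def stop_codon_tally(table: GenomeTable) -> dict[str, int]:
    """Tally annotated stop codons of the PCGs (from table metadata)."""
    tally: dict[str, int] = {}
    for r in table.genes:
        if r.feature_class == "PCG" and r.stop_codon:
            tally[r.stop_codon] = tally.get(r.stop_codon, 0) + 1
    return tally


def trna_size_range(table: GenomeTable) -> tuple[int, int]:
    sizes = [r.length for r in table.genes if r.feature_class == "tRNA"]
    if not sizes:
        raise ValueError("no tRNAs in table")
    return min(sizes), max(sizes)
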