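"""Gene-order algebra on circular signed permutations of mitochondrial genes.

A :class:`GeneOrder` is the circular sequence of the 37 mt genes with their
transcription orientations read along the majority (J) strand.  The control
region (CR) is carried as positional metadata, never as a gene: it does not
participate in adjacencies, but it does interrupt the gene run it sits in.

Two adjacency conventions are provided:

``signed-circular``
    Orientation-aware adjacencies on the full circle, with the equivalence
    (x, y) == (-y, -x) (reading the other strand), CR excluded; an n-gene
    order has n adjacencies.  This is the convention under which the
    breakpoint counts of the eriophyoid study are reproduced against the
    Limulus-type arthropod ancestral arrangement, and it is the default.

``unsigned-linear-cox1``
    Unordered gene-name pairs on the order linearized at cox1 (the adjacency
    spanning the cut is dropped), CR excluded; n-1 pairs.  Provided for
    comparison; it yields different (smaller) distances on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

SignedGene = tuple[str, int]  # (gene name, +1 for J / -1 for N)

CONVENTIONS = ("signed-circular", "unsigned-linear-cox1")


def _flip(g: SignedGene) -> SignedGene:
    return (g[0], -g[1])


@dataclass(frozen=True)
class GeneOrder:
    """Circular signed gene order of one genome (J-strand reading)."""

    taxon: str
    genes: tuple[SignedGene, ...]
    #: gene immediately 5' of the control region, or None if CR not retained
    cr_after: str | None = None

    def __post_init__(self):
        names = [g for g, _ in self.genes]
        if not names:
            raise ValueError("empty gene order")
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate genes in order: {sorted(dup)}")
        if self.cr_after is not None and self.cr_after not in names:
            raise ValueError(f"cr_after gene {self.cr_after!r} not in order")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_names(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def reverse_complement(self) -> "GeneOrder":
        """The same circle read along the opposite strand."""
        rc = tuple(_flip(g) for g in reversed(self.genes))
        cr = None
        if self.cr_after is not None:
            i = [g for g, _ in self.genes].index(self.cr_after)
            cr = self.genes[(i + 1) % len(self.genes)][0]
        return GeneOrder(self.taxon, rc, cr)

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.genes)
        return GeneOrder(self.taxon, self.genes[k:] + self.genes[:k], self.cr_after)

    def linearized_at(self, gene: str) -> "GeneOrder":
        names = [g for g, _ in self.genes]
        if gene not in names:
            raise ValueError(f"{gene} absent from order of {self.taxon}")
        return self.rotated(names.index(gene))

    def _canonical(self) -> tuple[SignedGene, ...]:
        cands = []
        for order in (self.genes, tuple(_flip(g) for g in reversed(self.genes))):
            for k in range(len(order)):
                cands.append(order[k:] + order[:k])
        return min(cands)

    def equivalent(self, other: "GeneOrder") -> bool:
        """Equality up to rotation and strand reading (CR position ignored)."""
        return self._canonical() == other._canonical()

    # -- exchange format -------------------------------------------------
    def to_tokens(self) -> str:
        toks = []
        for name, ori in self.genes:
            toks.append(("-" if ori < 0 else "") + name)
            if self.cr_after == name:
                toks.append("CR")
        return " ".join(toks)


@dataclass(frozen=True)
class AdjacencySet:
    """The neighbor pairs of one gene order under a stated convention."""

    convention: str
    pairs: frozenset

    def __len__(self) -> int:
        return len(self.pairs)

    def difference(self, other: "AdjacencySet") -> "AdjacencySet":
        if self.convention != other.convention:
            raise ValueError("cannot compare adjacency sets under different conventions")
        return AdjacencySet(self.convention, self.pairs - other.pairs)


@dataclass(frozen=True)
class DerivedCluster:
    """A maximal run of shared derived adjacencies (candidate synapomorphy)."""

    genes: tuple[SignedGene, ...]
    support: tuple[str, ...]
    absent_from: tuple[str, ...]

    @property
    def label(self) -> str:
        return "-".join(n for n, _ in self.genes)


def canonical_signed_pair(a: SignedGene, b: SignedGene) -> tuple[SignedGene, SignedGene]:
    """Canonical form of a signed adjacency under (x,y) == (-y,-x)."""
    return min((a, b), (_flip(b), _flip(a)))


def ordered_adjacencies(order: GeneOrder, cr_breaks: bool = True) -> list[tuple[SignedGene, SignedGene]]:
    """Strict ordered-orientation neighbor pairs around the circle.

    With ``cr_breaks`` the pair interrupted by the control region is omitted:
    two genes separated by the CR are not in physical contact.
    """
    n = len(order.genes)
    out = []
    for i in range(n):
        a, b = order.genes[i], order.genes[(i + 1) % n]
        if cr_breaks and order.cr_after == a[0]:
            continue
        out.append((a, b))
    return out


def adjacency_set(order: GeneOrder, convention: str = "signed-circular") -> AdjacencySet:
    """Extract the adjacency set of a gene order under a convention (CR excluded)."""
    if convention == "signed-circular":
        pairs = frozenset(canonical_signed_pair(a, b) for a, b in ordered_adjacencies(order, cr_breaks=False))
        return AdjacencySet(convention, pairs)
    if convention == "unsigned-linear-cox1":
        oriented = order
        names = dict(order.genes)
        if "cox1" not in names:
            raise ValueError(f"cox1 absent from order of {order.taxon}")
        if names["cox1"] < 0:  # canonical reading: the one with cox1 on +
            oriented = order.reverse_complement()
        lin = oriented.linearized_at("cox1").genes
        pairs = frozenset(frozenset((lin[i][0], lin[i + 1][0])) for i in range(len(lin) - 1))
        return AdjacencySet(convention, pairs)
    raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")


def _check_same_gene_set(target: GeneOrder, reference: GeneOrder) -> None:
    if target.gene_names != reference.gene_names:
        diff = sorted(target.gene_names ^ reference.gene_names)
        raise ValueError(f"gene sets differ between {target.taxon} and {reference.taxon}: {diff}")


def derived_adjacencies(target: GeneOrder, reference: GeneOrder,
                        convention: str = "signed-circular") -> AdjacencySet:
    """Adjacencies of the target absent from the reference."""
    _check_same_gene_set(target, reference)
    return adjacency_set(target, convention).difference(adjacency_set(reference, convention))


def breakpoint_distance(target: GeneOrder, reference: GeneOrder,
                        convention: str = "signed-circular") -> int:
    """Number of target adjacencies not present in the reference.

    Zero iff the two orders are identical up to rotation and strand reading.
    """
    return len(derived_adjacencies(target, reference, convention))


def _strict_pairs(order: GeneOrder) -> set[tuple[SignedGene, SignedGene]]:
    return set(ordered_adjacencies(order, cr_breaks=True))


def shared_derived_clusters(targets: Sequence[GeneOrder], reference: GeneOrder,
                            screen: Sequence[GeneOrder] | None = None) -> list[DerivedCluster]:
    """Chain shared derived adjacencies of the targets into maximal runs.

    An adjacency (strict ordered-orientation; no strand folding, so that a
    relocated-and-inverted block chains as one run) is a candidate when it is
    present in every target and absent from the reference.  When a screen of
    further arrangements is given, candidates found in any screened
    arrangement are discarded before chaining — a character shared with taxa
    outside the focal group is not a shared derived character of the group.
    Runs are reported 5'->3' on the reading strand of the first target.
    """
    if not targets:
        raise ValueError("at least one target order required")
    for t in targets:
        _check_same_gene_set(t, reference)
    ref_pairs = _strict_pairs(reference)
    shared = set.intersection(*(_strict_pairs(t) for t in targets)) - ref_pairs
    screened_names: tuple[str, ...] = ()
    if screen:
        screened_names = tuple(s.taxon for s in screen)
        screen_pairs = set().union(*(_strict_pairs(s) for s in screen))
        shared -= screen_pairs

    succ = {a: b for a, b in shared}
    pred = {b: a for a, b in shared}
    clusters = []
    seen: set[SignedGene] = set()

    def walk(head: SignedGene) -> None:
        run = [head]
        seen.add(head)
        cur = head
        while cur in succ and succ[cur] not in seen:
            cur = succ[cur]
            run.append(cur)
            seen.add(cur)
        if len(run) >= 2:
            clusters.append(DerivedCluster(
                genes=tuple(run),
                support=tuple(t.taxon for t in targets),
                absent_from=(reference.taxon,) + screened_names,
            ))

    for head in sorted(a for a in succ if a not in pred):
        walk(head)
    for node in sorted(succ):  # leftovers are cycles (whole circle derived)
        if node not in seen:
            walk(node)
    clusters.sort(key=lambda c: (-len(c.genes), c.label))
    return clusters


def contains_run(order: GeneOrder, run: Sequence[SignedGene]) -> bool:
    """True if ``run`` occurs as a contiguous ordered-orientation run (either
    strand reading, circularly, not interrupted by the CR)."""
    run = tuple(run)
    for reading in (order, order.reverse_complement()):
        pairs = set(ordered_adjacencies(reading, cr_breaks=True))
        if len(run) == 1:
            if run[0] in reading.genes:
                return True
            continue
        if all((run[i], run[i + 1]) in pairs for i in range(len(run) - 1)):
            return True
    return False


# -- arrangement exchange format ------------------------------------------

def parse_arrangement_line(line: str) -> GeneOrder:
    from .vocab import canonical_gene_name

    taxon, _, rest = line.partition("\t")
    toks = rest.split()
    if not taxon or not toks:
        raise ValueError(f"malformed arrangement line: {line!r}")
    genes: list[SignedGene] = []
    cr_after = None
    for tok in toks:
        ori = -1 if tok.startswith("-") else 1
        name = tok.lstrip("-")
        if name.upper() == "CR":
            if not genes:
                cr_after = "__leading__"
            else:
                cr_after = genes[-1][0]
            continue
        genes.append((canonical_gene_name(name), ori))
    if cr_after == "__leading__":  # CR printed first: it follows the last gene on the circle
        cr_after = genes[-1][0]
    return GeneOrder(taxon, tuple(genes), cr_after)


def read_arrangements(path_or_text) -> dict[str, GeneOrder]:
    """Read the one-genome-per-line exchange format (``taxon<TAB>gene ...``)."""
    import os

    text = path_or_text
    if isinstance(path_or_text, (str, os.PathLike)) and os.path.exists(str(path_or_text)):
        with open(path_or_text) as fh:
            text = fh.read()
    orders = {}
    for line in str(text).splitlines():
        line = line.strip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        o = parse_arrangement_line(line)
        if o.taxon in orders:
            raise ValueError(f"duplicate taxon {o.taxon!r} in arrangement file")
        orders[o.taxon] = o
    return orders


def write_arrangements(orders: Iterable[GeneOrder], path=None, header: str | None = None) -> str:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(f"{o.taxon}\t{o.to_tokens()}" for o in orders)
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
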