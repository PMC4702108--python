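"""Seed-deterministic generators: rearranged gene orders along trees,
annotated genomes with sequences, and tRNAs of known arm architecture.

These provide ground truth for every analysis stage: an evolved scenario
records the exact event history so leaf orders can be replayed; a generated
tRNA folds back to its specification under clean margins; a generated genome
parses back into the order and gap structure it was built from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from . import vocab
from .annotation import AnnotationRecord, GenomeTable
from .gene_order import GeneOrder, SignedGene
from .trna import FoldingThresholds, fold_best

DEFAULT_EVENT_MIX = {"inversion": 0.6, "transposition": 0.3, "inverse-transposition": 0.1}

_CR_TOKEN = ("CR", 1)


@dataclass(frozen=True)
class Event:
    """One rearrangement, with positions valid at its application time."""

    kind: str        # inversion | transposition | inverse-transposition
    start: int       # index of first element of the span
    length: int      # span length, 1 <= length <= m-1
    insert_at: int | None = None  # target gap (transpositions), in the depleted list


def _to_elements(order: GeneOrder) -> list[SignedGene]:
    els: list[SignedGene] = []
    for g in order.genes:
        els.append(g)
        if order.cr_after == g[0]:
            els.append(_CR_TOKEN)
    return els


def _from_elements(els: list[SignedGene], taxon: str) -> GeneOrder:
    genes = [e for e in els if e[0] != "CR"]
    cr_after = None
    if any(e[0] == "CR" for e in els):
        i = [e[0] for e in els].index("CR")
        cr_after = els[i - 1][0] if i else els[-1][0]
    return GeneOrder(taxon, tuple(genes), cr_after)


def apply_event(els: list[SignedGene], ev: Event) -> list[SignedGene]:
    """Apply one event to a circular element list (pure; returns a new list)."""
    m = len(els)
    if not 1 <= ev.length <= m - 1:
        raise ValueError(f"span length {ev.length} invalid for {m} elements")
    rot = els[ev.start:] + els[:ev.start]  # span now at the front
    span, rest = rot[:ev.length], rot[ev.length:]
    inv = [(g, -s) for g, s in reversed(span)]
    if ev.kind == "inversion":
        out = inv + rest
    elif ev.kind in ("transposition", "inverse-transposition"):
        if ev.insert_at is None or not 1 <= ev.insert_at <= len(rest):
            raise ValueError("transposition needs insert_at in [1, m-length]")
        moved = inv if ev.kind == "inverse-transposition" else span
        out = rest[:ev.insert_at] + moved + rest[ev.insert_at:]
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")
    # undo the rotation so positions stay interpretable
    return out[-ev.start:] + out[:-ev.start] if ev.start else out


def _draw_event(rng: np.random.Generator, m: int, mix: dict[str, float]) -> Event:
    kinds = sorted(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=probs / probs.sum()))]
    if kind != "inversion" and m < 4:
        kind = "inversion"  # a circle this small has no non-trivial transposition
    start = int(rng.integers(0, m))
    if kind == "inversion":
        return Event(kind, start, int(rng.integers(1, m)))  # span in [1, m-1]
    # a block moved to the complementary end of the circle is a rotation, i.e.
    # the identity; keep span <= m-2 and the landing gap strictly internal
    length = int(rng.integers(1, m - 1))
    insert_at = int(rng.integers(1, m - length))
    return Event(kind, start, length, insert_at)


def evolve_order(order: GeneOrder, n_events: int,
                 event_mix: dict[str, float] | None = None,
                 rng_seed: int | np.random.Generator = 0) -> tuple[GeneOrder, list[Event]]:
    """Apply ``n_events`` random rearrangements; the log suffices to replay.

    The CR is carried through events as an inert marker.  Span lengths are
    uniform in [1, m-1] over the m circular elements.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    mix = dict(event_mix or DEFAULT_EVENT_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("event mix weights must sum to 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    els = _to_elements(order)
    log: list[Event] = []
    for _ in range(n_events):
        ev = _draw_event(rng, len(els), mix)
        els = apply_event(els, ev)
        log.append(ev)
    return _from_elements(els, order.taxon), log


@dataclass
class RearrangementScenario:
    """Simulated rearrangement history along a rooted tree (ground truth)."""

    newick: str
    root_order: GeneOrder
    events: dict[str, list[Event]]       # edge (child-node label) -> events
    node_orders: dict[str, GeneOrder]    # every node, including internals
    leaf_orders: dict[str, GeneOrder]
    seed: int

    def replay(self) -> dict[str, GeneOrder]:
        """Re-derive all node orders from root_order and the event log."""
        import dendropy

        tree = dendropy.Tree.get(data=self.newick, schema="newick", preserve_underscores=True)
        out: dict[str, GeneOrder] = {}

        def down(node, order):
            label = _label_of(node)
            for ev in self.events.get(label, []):
                els = _to_elements(order)
                els = apply_event(els, ev)
                order = _from_elements(els, label)
            out[label] = replace(order, taxon=label)
            for child in node.child_nodes():
                down(child, out[label])

        down(tree.seed_node, self.root_order)
        return out


def _label_of(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def simulate_scenario(newick: str, events_per_edge: int, seed: int,
                      event_mix: dict[str, float] | None = None,
                      root_order: GeneOrder | None = None) -> RearrangementScenario:
    """Evolve a root order down a tree with a fixed event count per edge."""
    import dendropy

    if root_order is None:
        root_order = ancestral_arthropod_order()
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    # give unlabeled internal nodes stable names so edges are addressable
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"node{k}"
            k += 1
    newick_labeled = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()

    ss = np.random.SeedSequence(seed)
    events: dict[str, list[Event]] = {}
    node_orders: dict[str, GeneOrder] = {}

    nodes = list(tree.preorder_node_iter())
    child_seeds = ss.spawn(len(nodes))
    for node, child_seed in zip(nodes, child_seeds):
        label = _label_of(node)
        if node.parent_node is None:
            node_orders[label] = replace(root_order, taxon=label)
            events[label] = []
            continue
        parent = node_orders[_label_of(node.parent_node)]
        rng = np.random.default_rng(child_seed)
        evolved, log = evolve_order(parent, events_per_edge, event_mix, rng)
        node_orders[label] = replace(evolved, taxon=label)
        events[label] = log

    leaf_orders = {_label_of(l): node_orders[_label_of(l)] for l in tree.leaf_node_iter()}
    return RearrangementScenario(newick=newick_labeled, root_order=root_order,
                                 events=events, node_orders=node_orders,
                                 leaf_orders=leaf_orders, seed=seed)


def ancestral_arthropod_order() -> GeneOrder:
    """The packaged Limulus-type hypothetical arthropod ancestral arrangement."""
    from .fixtures import load_arrangements

    return load_arrangements()["ancestral_arthropod"]


# -- tRNA generation --------------------------------------------------------

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _wc_rev(seq: str) -> str:
    return "".join(_WC[c] for c in reversed(seq))


@dataclass(frozen=True)
class TrnaSpec:
    """Target architecture for a generated tRNA (ground truth)."""

    family: str
    d_arm: bool = True
    t_arm: bool = True
    d_stem: int = 3
    t_stem: int = 4
    d_loop: int = 5
    t_loop: int = 5
    d_mismatches: int = 0
    t_mismatches: int = 0
    acceptor_mismatches: int = 0
    anticodon_stem: int = 5
    d_replacement_len: int = 5
    t_replacement_len: int = 5

    @property
    def classification(self) -> str:
        if self.d_arm and self.t_arm:
            return "cloverleaf"
        if self.t_arm:
            return "D-armless"
        if self.d_arm:
            return "T-armless"
        return "armless"


def _rand_stem(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["G", "C"], size=n))


def _inject_mismatch(arm3: str, k: int) -> str:
    # replace with a base that can pair with nothing in the partner position
    out = list(arm3)
    out[k] = "A" if out[k] in "GT" else "C"
    return "".join(out)


def generate_trna(spec: TrnaSpec, seed: int = 0) -> str:
    """Emit a sequence that folds to ``spec`` under clean margins.

    Stems use G/C pairs (mismatches injected on the 3' side on request);
    replacement loops for lost arms are unpairable poly-A.
    """
    if spec.family not in vocab.FAMILY_ANTICODON:
        raise ValueError(f"unknown tRNA family {spec.family!r}")
    if not 2 <= spec.anticodon_stem <= 5:
        raise ValueError("anticodon stem must have 2-5 pairs")
    rng = np.random.default_rng(seed)
    anticodon = vocab.FAMILY_ANTICODON[spec.family]

    acc5 = _rand_stem(rng, 7)
    acc3 = _wc_rev(acc5)
    for k in range(spec.acceptor_mismatches):
        acc3 = _inject_mismatch(acc3, 2 * k + 1)

    def hairpin(stem: int, loop: int, mism: int) -> str:
        s5 = _rand_stem(rng, stem)
        loop_seq = "".join(rng.choice(["A", "A", "C"], size=loop))
        s3 = _wc_rev(s5)
        for k in range(mism):
            s3 = _inject_mismatch(s3, min(2 * k + 1, stem - 1))
        return s5 + loop_seq + s3

    d_region = (hairpin(spec.d_stem, spec.d_loop, spec.d_mismatches)
                if spec.d_arm else "A" * spec.d_replacement_len)
    t_region = (hairpin(spec.t_stem, spec.t_loop, spec.t_mismatches)
                if spec.t_arm else "A" * spec.t_replacement_len)

    ac5 = _rand_stem(rng, spec.anticodon_stem)
    ac_loop = "C" + "A" + anticodon + "A" + "A"
    ac_region = ac5 + ac_loop + _wc_rev(ac5)

    seq = acc5 + "AA" + d_region + "A" + ac_region + "A" + t_region + acc3
    if not 40 <= len(seq) <= 100:
        raise ValueError(f"spec not realizable: generated length {len(seq)} outside [40, 100]")
    return seq


def verify_trna(spec: TrnaSpec, seq: str,
                thresholds: FoldingThresholds | None = None) -> bool:
    """Round-trip check: does the sequence fold back to the spec's class?"""
    st = fold_best(seq, vocab.FAMILY_ANTICODON[spec.family],
                   thresholds or FoldingThresholds())
    return st.classification == spec.classification and st.anticodon == vocab.FAMILY_ANTICODON[spec.family]


# -- genome generation ------------------------------------------------------

_NON_STOP_CODONS = tuple(sorted(
    c for c in ("".join(x) for x in itertools.product("ACGT", repeat=3))
    if c not in vocab.INVERT_MITO.stop_codons))


def generate_genome(order: GeneOrder, seed: int = 0,
                    incomplete_stops: frozenset[str] | set[str] = frozenset(),
                    pcg_codons: tuple[int, int] = (50, 150),
                    rrna_len: tuple[int, int] = (250, 400),
                    cr_len: int = 60,
                    max_gap: int = 3) -> tuple[str, GenomeTable]:
    """Build a genome sequence plus matching annotation table from an order.

    PCGs get valid invertebrate-mt start/stop codons (genes named in
    ``incomplete_stops`` end in a bare T); tRNAs are generated cloverleafs
    carrying their family anticodon; coordinates tile the circle so the gap
    arithmetic holds exactly.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    records: list[AnnotationRecord] = []
    pos = 1

    def emit(name: str, fclass: str, strand: str | None, seq: str,
             anticodon: str | None = None, start_codon: str | None = None,
             stop_codon: str | None = None):
        nonlocal pos
        placed = vocab.revcomp(seq) if strand == "N" else seq
        parts.append(placed)
        records.append(AnnotationRecord(
            gene_name=name, feature_class=fclass, strand=strand,
            start=pos, end=pos + len(seq) - 1, anticodon=anticodon,
            start_codon=start_codon, stop_codon=stop_codon))
        pos += len(seq)

    def gap():
        nonlocal pos
        g = int(rng.integers(0, max_gap + 1))
        if g:
            parts.append("".join(rng.choice(list("ACGT"), size=g)))
            pos += g

    elements = _to_elements(order)
    for name, ori in elements:
        strand = "N" if ori < 0 else "J"
        if name == "CR":
            parts.append("".join(rng.choice(list("ACGT"), size=cr_len)))
            records.append(AnnotationRecord(
                gene_name="CR", feature_class="CR", strand=None,
                start=pos, end=pos + cr_len - 1))
            pos += cr_len
            gap()
            continue
        fclass = vocab.feature_class(name)
        if fclass == "PCG":
            ncod = int(rng.integers(*pcg_codons))
            body = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(ncod))
            start_codon = str(rng.choice(["ATG", "ATA", "ATT"]))
            if name in incomplete_stops:
                stop = "T"
            else:
                stop = str(rng.choice(["TAA", "TAG"]))
            emit(name, "PCG", strand, start_codon + body + stop,
                 start_codon=start_codon, stop_codon=stop)
        elif fclass == "rRNA":
            emit(name, "rRNA", strand,
                 "".join(rng.choice(list("ACGT"), size=int(rng.integers(*rrna_len)))))
        else:
            seq = generate_trna(TrnaSpec(family=name), seed=int(rng.integers(0, 2**31 - 1)))
            emit(name, "tRNA", strand, seq, anticodon=vocab.FAMILY_ANTICODON[name])
        gap()

    genome = "".join(parts)
    table = GenomeTable(taxon=order.taxon,
                        records=tuple(sorted(records, key=lambda r: (r.start, r.end, r.gene_name))),
                        genome_length=len(genome))
    return genome, table
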