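"""Ancestral gene-arrangement inference on a user-supplied rooted tree.

Each gene adjacency (signed-circular convention: a physical junction between
two gene extremities, identical from either strand reading) is treated as an
independent binary presence/absence character.  Standard two-pass Fitch
parsimony yields the most-parsimonious state set per internal node; candidate
ancestral arrangements are then assembled from the junctions confidently
present at a node.  Genes left without a junction, or with conflicting ones,
are reported as unplaced — mirroring the uncertainty the underlying study
expresses for trnQ and trnY in the acariform ancestor.

Correlations between adjacency characters are ignored; the assembled
arrangement is a candidate summary, not a joint reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

from .gene_order import (AdjacencySet, GeneOrder, SignedGene, adjacency_set,
                         canonical_signed_pair)

Pair = tuple[SignedGene, SignedGene]


def pair_label(pair: Pair) -> str:
    (x, sx), (y, sy) = pair
    f = lambda g, s: f"{g}({'+' if s > 0 else '-'})"
    return f(x, sx) + "|" + f(y, sy)


@dataclass(frozen=True)
class AdjacencyCharacterMatrix:
    """Presence/absence of each observed adjacency per taxon."""

    taxa: tuple[str, ...]
    characters: tuple[Pair, ...]
    states: dict[str, frozenset[Pair]]  # taxon -> set of present adjacencies

    def present(self, taxon: str, char: Pair) -> bool:
        return char in self.states[taxon]


def build_matrix(orders: Sequence[GeneOrder], convention: str = "signed-circular") -> AdjacencyCharacterMatrix:
    """Character matrix over the union of adjacencies observed in ``orders``."""
    if not orders:
        raise ValueError("no gene orders supplied")
    taxa = [o.taxon for o in orders]
    dup = {t for t in taxa if taxa.count(t) > 1}
    if dup:
        raise ValueError(f"duplicate taxon labels: {sorted(dup)}")
    if convention != "signed-circular":
        raise ValueError("character matrices are defined for the signed-circular convention")
    states = {o.taxon: frozenset(adjacency_set(o, convention).pairs) for o in orders}
    union = sorted(set().union(*states.values()))
    return AdjacencyCharacterMatrix(tuple(taxa), tuple(union), states)


@dataclass
class AncestralStateReport:
    """Fitch reconstruction: per internal node the confidently present,
    confidently absent and ambiguous characters; per character the
    most-parsimonious number of changes."""

    node_states: dict[str, dict[str, set[Pair]]]  # node -> {"present"|"absent"|"ambiguous"}
    changes: dict[Pair, int]

    def present_set(self, node: str) -> set[Pair]:
        return set(self.node_states[node]["present"])

    def ambiguous_set(self, node: str) -> set[Pair]:
        return set(self.node_states[node]["ambiguous"])

    def to_records(self) -> list[dict]:
        rows = []
        for node, sets in self.node_states.items():
            for kind in ("present", "absent", "ambiguous"):
                for pair in sorted(sets[kind]):
                    rows.append({"node": node, "adjacency": pair_label(pair), "state": kind})
        return rows


def load_tree(source: str) -> dendropy.Tree:
    """Read a rooted Newick tree (path or literal string)."""
    import os

    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _node_label(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    return f"node{counter[0]}"


def fitch_ancestral_states(matrix: AdjacencyCharacterMatrix, tree: dendropy.Tree,
                           outgroup: str | None = None) -> AncestralStateReport:
    """Two-pass Fitch parsimony per adjacency character.

    Root-state ties are broken toward the outgroup's state when an outgroup
    taxon is flagged; otherwise ambiguity is reported, never silently
    resolved.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaves != set(matrix.taxa):
        raise ValueError(
            f"tree leaves and matrix taxa differ: only-tree={sorted(leaves - set(matrix.taxa))}, "
            f"only-matrix={sorted(set(matrix.taxa) - leaves)}")
    if outgroup is not None and outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")

    counter = [0]
    labels = {id(n): _node_label(n, counter) for n in tree.preorder_node_iter()}
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    node_states = {labels[id(n)]: {"present": set(), "absent": set(), "ambiguous": set()}
                   for n in internal}
    changes: dict[Pair, int] = {}

    for char in matrix.characters:
        down: dict[int, frozenset[int]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                down[id(node)] = frozenset({1 if matrix.present(node.taxon.label, char) else 0})
                continue
            sets = [down[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            down[id(node)] = inter if inter else frozenset.union(*sets)
        # change count via a small Sankoff DP: exact also on polytomies, where
        # counting union events of the downpass would overshoot
        changes[char] = _min_changes(tree, down)

        final: dict[int, frozenset[int]] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            s = down[id(node)]
            if len(s) == 1:
                final[id(node)] = s
            elif node.parent_node is None:
                if outgroup is not None:
                    og = 1 if matrix.present(outgroup, char) else 0
                    final[id(node)] = frozenset({og}) if og in s else s
                else:
                    final[id(node)] = s
            else:
                p = final[id(node.parent_node)]
                final[id(node)] = p if (len(p) == 1 and next(iter(p)) in s) else s
            st = final[id(node)]
            lab = labels[id(node)]
            if st == frozenset({1}):
                node_states[lab]["present"].add(char)
            elif st == frozenset({0}):
                node_states[lab]["absent"].add(char)
            else:
                node_states[lab]["ambiguous"].add(char)

    return AncestralStateReport(node_states=node_states, changes=changes)


def _min_changes(tree: dendropy.Tree, leaf_down: dict) -> int:
    """Sankoff DP for a binary character (unit costs); exact minimum."""
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = leaf_down[id(node)]
            cost[id(node)] = (0.0 if 0 in s else float("inf"),
                              0.0 if 1 in s else float("inf"))
            continue
        c0 = c1 = 0.0
        for child in node.child_nodes():
            k0, k1 = cost[id(child)]
            c0 += min(k0, k1 + 1)
            c1 += min(k1, k0 + 1)
        cost[id(node)] = (c0, c1)
    return int(min(cost[id(tree.seed_node)]))


# -- arrangement assembly ---------------------------------------------------

@dataclass
class AssemblyResult:
    """Ordered fragments assembled from an adjacency set, with conflicts."""

    fragments: list[tuple[SignedGene, ...]]
    unplaced: list[str]      # genes isolated or in conflict
    conflicts: list[str]     # subset of unplaced: genes with over-connected ends
    is_circular: bool        # True when a single conflict-free circle covers all genes

    def fragment_labels(self) -> list[str]:
        out = []
        for frag in self.fragments:
            out.append(" ".join(("-" if s < 0 else "") + g for g, s in frag))
        return out


def _ends(pair: Pair) -> tuple[tuple[str, str], tuple[str, str]]:
    (x, sx), (y, sy) = pair
    return (x, "3" if sx > 0 else "5"), (y, "5" if sy > 0 else "3")


def assemble_arrangement(present: Iterable[Pair], genes: Iterable[str]) -> AssemblyResult:
    """Build maximal unambiguous gene runs from a set of junctions.

    Every junction joins a 3'/5' extremity of one gene to an extremity of
    another.  An extremity touched by more than one junction is a conflict:
    the owning gene is reported unplaced and its junctions are discarded.
    Genes with no usable junction are unplaced (isolated).  Conflicts are
    data, not failures.
    """
    genes = sorted(set(genes))
    junctions = {tuple(sorted(_ends(canonical_signed_pair(*p)))) for p in present}
    touch: dict[tuple[str, str], list] = {}
    for j in junctions:
        for end in j:
            touch.setdefault(end, []).append(j)
    conflicts = sorted({end[0] for end, js in touch.items() if len(js) > 1})
    usable = [j for j in junctions if not any(e[0] in conflicts for e in j)]

    nbr: dict[tuple[str, str], tuple[str, str]] = {}
    for a, b in usable:
        nbr[a] = b
        nbr[b] = a

    placed: set[str] = set()
    fragments: list[tuple[SignedGene, ...]] = []

    def other_end(end):
        return (end[0], "5" if end[1] == "3" else "3")

    def walk(start_gene: str, enter_end: tuple[str, str]) -> tuple[SignedGene, ...]:
        frag: list[SignedGene] = []
        end = enter_end
        while True:
            g = end[0]
            frag.append((g, 1 if end[1] == "5" else -1))
            placed.add(g)
            out = other_end(end)
            nxt = nbr.get(out)
            if nxt is None or nxt[0] in placed:
                break
            end = nxt
        return tuple(frag)

    linkable = {g for g in genes if g not in conflicts and
                (((g, "5") in nbr) or ((g, "3") in nbr))}
    # open paths first: start at genes with exactly one connected end
    for g in sorted(linkable):
        if g in placed:
            continue
        has5, has3 = (g, "5") in nbr, (g, "3") in nbr
        if has5 != has3:
            fragments.append(walk(g, (g, "5") if has3 else (g, "3")))
    circular = False
    for g in sorted(linkable):  # leftovers are cycles
        if g not in placed:
            frag = walk(g, (g, "5"))
            fragments.append(frag)
            if len(frag) == len(genes):
                circular = True

    unplaced = sorted(set(genes) - placed)
    return AssemblyResult(fragments=fragments, unplaced=unplaced,
                          conflicts=conflicts, is_circular=circular and not unplaced)
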