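"""Rooted trees: the species tree and light-weight gene trees.

The species tree is immutable after construction and assigns every node a
stable integer ``node_id`` in post-order of the input Newick, so that
downstream placements are reproducible across runs.  Gene trees are small
mutable node structures (children / branch length / bootstrap support on the
branch above) that support the rooting operations the placement stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = ["SpeciesTree", "GeneTreeNode", "read_newick", "write_newick"]


class SpeciesTree:
    """A rooted species phylogeny with stable post-order node ids.

    Tips are labelled with species ids.  Branches are identified as
    ``(parent_id, child_id)`` pairs.  The tree may be binary or
    multifurcating.
    """

    def __init__(self, dendropy_tree: dendropy.Tree):
        self._assign(dendropy_tree)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        from dendropy.dataio.newickreader import NewickReader

        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip label in Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _assign(self, tree: dendropy.Tree) -> None:
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent: list[Optional[int]] = [None] * self.n_nodes
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.label: list[Optional[str]] = [None] * self.n_nodes
        self.branch_length: list[Optional[float]] = [None] * self.n_nodes
        labels_seen: set[str] = set()
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("species tree has an unlabelled tip")
                lbl = nd.taxon.label.replace(" ", "_")
                if lbl in labels_seen:
                    raise ValueError(f"duplicate tip label: {lbl!r}")
                labels_seen.add(lbl)
                self.label[i] = lbl
            self.branch_length[i] = nd.edge.length
        self.root_id = index[id(tree.seed_node)]
        self.tip_ids = {self.label[i]: i for i in range(self.n_nodes) if self.label[i]}
        # depth from root; subtree species bitmask per node
        self.depth = [0] * self.n_nodes
        for i in reversed(range(self.n_nodes)):  # reverse post-order = pre-order
            p = self.parent[i]
            if p is not None:
                self.depth[i] = self.depth[p] + 1
        self._bit = {sp: 1 << k for k, sp in enumerate(sorted(self.tip_ids))}
        self.mask = [0] * self.n_nodes
        for i in range(self.n_nodes):
            if self.label[i]:
                self.mask[i] = self._bit[self.label[i]]
            for c in self.children[i]:
                self.mask[i] |= self.mask[c]

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return sorted(self.tip_ids)

    def species_mask(self, species: Iterable[str]) -> int:
        m = 0
        for sp in species:
            if sp not in self._bit:
                raise KeyError(f"species {sp!r} is not a tip of the species tree")
            m |= self._bit[sp]
        return m

    def mrca(self, species: Iterable[str]) -> int:
        """Node id of the most recent common ancestor of a species set."""
        m = self.species_mask(species)
        if m == 0:
            raise ValueError("empty species set")
        node = self.root_id
        while True:
            nxt = [c for c in self.children[node] if self.mask[c] & m == m]
            if not nxt:
                return node
            node = nxt[0]

    def is_strict_ancestor(self, anc: int, node: int) -> bool:
        """True iff ``anc`` is a proper ancestor of ``node``."""
        p = self.parent[node]
        while p is not None:
            if p == anc:
                return True
            p = self.parent[p]
        return False

    def path_up(self, lower: int, upper: int) -> list[tuple[int, int]]:
        """Branches (parent, child) from ``lower`` up to ``upper`` (exclusive).

        ``upper`` must be an ancestor of (or equal to) ``lower``.
        """
        branches = []
        node = lower
        while node != upper:
            p = self.parent[node]
            if p is None:
                raise ValueError("upper is not an ancestor of lower")
            branches.append((p, node))
            node = p
        return branches

    def branches(self) -> list[tuple[int, int]]:
        return [
            (self.parent[i], i) for i in range(self.n_nodes) if self.parent[i] is not None
        ]

    def branch_name(self, branch: tuple[int, int]) -> str:
        """Human-readable branch name: stem of the child's species set."""
        _, child = branch
        sps = [sp for sp, b in self._bit.items() if self.mask[child] & b]
        return "stem(" + "+".join(sorted(sps)) + ")"

    def node_species(self, node: int) -> frozenset[str]:
        return frozenset(sp for sp, b in self._bit.items() if self.mask[node] & b)

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                s = self.label[i]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            bl = self.branch_length[i]
            if bl is not None:
                s += f":{bl:.10g}"
            return s

        return rec(self.root_id) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({len(self.tip_ids)} tips, {self.n_nodes} nodes)"


def read_newick(path) -> SpeciesTree:
    """Read a rooted Newick species tree; node ids assigned in post-order."""
    return SpeciesTree.from_file(path)


def write_newick(tree: SpeciesTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Gene trees


@dataclass
class GeneTreeNode:
    """Node of a (gene) tree.

    ``length`` and ``support`` describe the branch above the node; support is
    a bootstrap percentage in [0, 100] and is meaningful on internal branches
    only.  Tips carry ``name`` (gene id) and ``species``.
    """

    name: Optional[str] = None
    species: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["GeneTreeNode"] = field(default_factory=list)
    parent: Optional["GeneTreeNode"] = None
    # filled by classify_nodes:
    species_node: Optional[int] = None
    label: Optional[str] = None  # duplication | speciation | dubious

    # -- structure ---------------------------------------------------------

    def add(self, child: "GeneTreeNode") -> "GeneTreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["GeneTreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def tips(self) -> list["GeneTreeNode"]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def find_tip(self, name: str) -> "GeneTreeNode":
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(name)

    def mrca(self, name_a: str, name_b: str) -> "GeneTreeNode":
        """MRCA of two tips in this rooted tree."""
        anc_a = []
        n = self.find_tip(name_a)
        while n is not None:
            anc_a.append(n)
            n = n.parent
        aset = set(map(id, anc_a))
        n = self.find_tip(name_b)
        while n is not None:
            if id(n) in aset:
                return n
            n = n.parent
        raise ValueError("tips do not share an ancestor")

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(n: GeneTreeNode) -> str:
            if n.is_tip:
                s = n.name or ""
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if n.support is not None:
                    s += f"{n.support:g}"
            return s + f":{n.length:.10g}"

        return rec(self) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        k = len(self.tips())
        return f"GeneTreeNode({k} tips)"
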