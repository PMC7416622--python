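"""Placing duplication events on the species tree from anchor-bearing gene trees.

For every gene family that contains at least one anchor pair and at least
one outgroup gene, a gene tree is built (neighbor joining on
Poisson-corrected amino-acid distances, with a codon-column-resampling
bootstrap), rooted on the outgroup when its genes are monophyletic and at
the midpoint otherwise, and reconciled against the species tree by LCA
mapping.  Internal nodes are classified as duplication (child clades share
a species), speciation (no shared species and the node's map is a strict
ancestor of both children's maps) or dubious (no shared species but
incongruent with the species phylogeny).  Each anchor pair coalescing at a
duplication node is circumscribed between that node's species map (lower
bound) and the map of its first speciation ancestor (upper bound); when the
two bounds are joined by a single species-tree branch the duplication is
assigned to that branch, with the bootstrap support of the branch leading
to the anchor pair's coalescent node attached.  Tracing toward the upper
bound continues past dubious nodes (the number skipped is logged per
placement).
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .ks import CODON_AA
from .model import CodingSequenceSet, GeneFamily
from .tree import GeneTreeNode, SpeciesTree

__all__ = [
    "filter_families_for_placement",
    "nj_tree",
    "poisson_distance_matrix",
    "bootstrap_support",
    "build_gene_tree",
    "root_gene_tree",
    "classify_nodes",
    "Placement",
    "place_anchor",
    "count_events_per_branch",
    "place_families",
]

_AA_CODE = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY*X")}


# ---------------------------------------------------------------------------
# Family filtering


def filter_families_for_placement(
    families: Sequence[GeneFamily],
    anchors: Iterable[Tuple[str, str]],
    anchor_ks: Dict[Tuple[str, str], float],
    outgroup_species: str,
    species_of: Dict[str, str],
    max_size: int = 300,
    max_ks: float = 5.0,
) -> Tuple[List[GeneFamily], Dict[str, List[Tuple[str, str]]]]:
    """Select and merge the families whose gene trees date anchor pairs.

    Anchor pairs with Ks > ``max_ks`` (or saturated/undefined) are removed
    first.  When a surviving anchor spans two families the families are
    merged (a family-assignment artifact).  Retained families have at most
    ``max_size`` members, at least one surviving anchor pair and at least
    one outgroup gene.  Returns (families, anchors per family id).
    """
    surviving = []
    for a, b in anchors:
        pair = (a, b) if a < b else (b, a)
        ks = anchor_ks.get(pair, math.nan)
        if not math.isfinite(ks) or ks > max_ks:
            continue
        surviving.append(pair)

    fam_of: Dict[str, int] = {}
    for i, fam in enumerate(families):
        for m in fam.members:
            fam_of[m] = i

    # union-find over family indices, driven by anchors spanning families
    parent = list(range(len(families)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in surviving:
        if a in fam_of and b in fam_of:
            ra, rb = find(fam_of[a]), find(fam_of[b])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    merged_members: Dict[int, List[str]] = defaultdict(list)
    for i, fam in enumerate(families):
        merged_members[find(i)].extend(fam.members)

    out_families: List[GeneFamily] = []
    out_anchors: Dict[str, List[Tuple[str, str]]] = {}
    for k, root in enumerate(sorted(merged_members)):
        members = sorted(set(merged_members[root]))
        fam_anchors = sorted(
            p for p in surviving if p[0] in set(members) and p[1] in set(members)
        )
        if not fam_anchors:
            continue
        if len(members) > max_size:
            continue
        if not any(species_of.get(m) == outgroup_species for m in members):
            continue
        fam = GeneFamily(
            family_id=f"pfam{len(out_families):04d}",
            members=members,
            species={m: species_of[m] for m in members},
        )
        out_families.append(fam)
        out_anchors[fam.family_id] = fam_anchors
    return out_families, out_anchors


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def _translate(cds: str) -> str:
    return "".join(CODON_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _aa_matrix(members: Sequence[str], cds: CodingSequenceSet) -> np.ndarray:
    rows = []
    length = None
    for m in members:
        aa = _translate(cds[m])
        if length is None:
            length = len(aa)
        elif len(aa) != length:
            raise ValueError("gene family sequences differ in length (no indels expected)")
        rows.append([_AA_CODE.get(c, _AA_CODE["X"]) for c in aa])
    return np.asarray(rows, dtype=np.int8)


def _pdist(X: np.ndarray) -> np.ndarray:
    n = len(X)
    if n <= 64:
        return (X[:, None, :] != X[None, :, :]).mean(axis=2)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = (X != X[i]).mean(axis=1)
    return d


def poisson_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Poisson-corrected amino-acid distance -ln(1-p); saturated pairs are
    capped at (max finite distance + 1)."""
    p = _pdist(X)
    with np.errstate(divide="ignore"):
        d = -np.log(1.0 - p)
    finite = d[np.isfinite(d)]
    cap = (finite.max() if len(finite) else 0.0) + 1.0
    d[~np.isfinite(d)] = cap
    np.fill_diagonal(d, 0.0)
    return d


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> GeneTreeNode:
    """Canonical neighbor joining; returns an unrooted tree represented with
    a trifurcating (or, for 2 tips, bifurcating) top node.

    Deterministic: ties in the Q criterion resolve to the smallest (i, j).
    """
    n = len(labels)
    if n < 2:
        raise ValueError("nj_tree needs at least 2 tips")
    nodes: List[GeneTreeNode] = [GeneTreeNode(name=lab) for lab in labels]
    if n == 2:
        root = GeneTreeNode()
        for k in range(2):
            nodes[k].length = float(dist[0, 1]) / 2.0
            root.add(nodes[k])
        return root
    D = np.asarray(dist, dtype=float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new = GeneTreeNode()
        nodes[ai].length = max(li, 0.0)
        nodes[aj].length = max(lj, 0.0)
        new.add(nodes[ai])
        new.add(nodes[aj])
        # distances to the new node
        newdist = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, newdist])
        D = np.hstack([D, np.append(newdist, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    root = GeneTreeNode()
    a, b, c = active
    da = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    db = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    dc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, l in ((a, da), (b, db), (c, dc)):
        nodes[idx].length = max(float(l), 0.0)
        root.add(nodes[idx])
    return root


# ---------------------------------------------------------------------------
# Bootstrap support


def _bipartitions(root: GeneTreeNode, ref: str) -> Dict[frozenset, GeneTreeNode]:
    """Canonical unrooted bipartitions: tip set of each internal edge, taken
    on the side NOT containing the reference tip.  Trivial splits skipped."""
    all_tips = frozenset(root.tip_names())
    out: Dict[frozenset, GeneTreeNode] = {}
    for node in root.postorder():
        if node is root or node.is_tip:
            continue
        below = frozenset(node.tip_names())
        side = below if ref not in below else all_tips - below
        if 2 <= len(below) <= len(all_tips) - 2:  # non-trivial split
            out[side] = node
    return out


def bootstrap_support(
    root: GeneTreeNode,
    X: np.ndarray,
    labels: Sequence[str],
    B: int = 200,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GeneTreeNode:
    """Attach column-resampling bootstrap percentages to internal branches.

    Each replicate resamples alignment columns with replacement, recomputes
    Poisson-corrected distances and the NJ tree, and counts recovered
    bipartitions.  Deterministic given the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ref = min(labels)
    target = _bipartitions(root, ref)
    counts = {bp: 0 for bp in target}
    L = X.shape[1]
    for _ in range(B):
        cols = rng.integers(0, L, L)
        rep = nj_tree(poisson_distance_matrix(X[:, cols]), labels)
        for bp in _bipartitions(rep, ref):
            if bp in counts:
                counts[bp] += 1
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / B
    return root


# ---------------------------------------------------------------------------
# Rooting


def _to_undirected(root: GeneTreeNode):
    """Adjacency view of a (possibly trifurcating-top) tree.

    Returns (nodes, adj) with adj[id(n)] = [(neighbor, length, support)].
    """
    adj: Dict[int, List[Tuple[GeneTreeNode, float, Optional[float]]]] = defaultdict(list)
    nodes = list(root.postorder())
    for n in nodes:
        for c in n.children:
            adj[id(n)].append((c, c.length, c.support))
            adj[id(c)].append((n, c.length, c.support))
    return nodes, adj


def _orient(node: GeneTreeNode, came_from: Optional[GeneTreeNode], adj, length: float, support) -> GeneTreeNode:
    out = GeneTreeNode(
        name=node.name, species=node.species, length=length, support=support
    )
    for nb, ln, sup in adj[id(node)]:
        if came_from is not None and nb is came_from:
            continue
        out.add(_orient(nb, node, adj, ln, sup))
    return out


def _root_on_edge(
    tree: GeneTreeNode, child: GeneTreeNode, parent: GeneTreeNode, offset: float
) -> GeneTreeNode:
    """Root on the edge between ``child`` and ``parent``; ``offset`` is the
    distance from ``child`` to the new root."""
    _, adj = _to_undirected(tree)
    edge = next(e for e in adj[id(child)] if e[0] is parent)
    length, support = edge[1], edge[2]
    offset = min(max(offset, 0.0), length)
    root = GeneTreeNode()
    root.add(_orient(child, parent, adj, offset, support))
    root.add(_orient(parent, child, adj, length - offset, support))
    return root


def _tip_paths(root: GeneTreeNode):
    """All tip-to-tip path lengths with the path's edge list (small trees)."""
    _, adj = _to_undirected(root)
    tips = root.tips()
    dist: Dict[Tuple[str, str], Tuple[float, List[Tuple[GeneTreeNode, GeneTreeNode, float]]]] = {}

    def walk(start: GeneTreeNode):
        stack = [(start, None, 0.0, [])]
        while stack:
            node, came, d, path = stack.pop()
            if node.is_tip and node is not start:
                dist[(start.name, node.name)] = (d, path)
            for nb, ln, _sup in adj[id(node)]:
                if came is not None and nb is came:
                    continue
                stack.append((nb, node, d + ln, path + [(node, nb, ln)]))

    for t in tips:
        walk(t)
    return dist


def root_gene_tree(tree: GeneTreeNode, outgroup_species: str) -> GeneTreeNode:
    """Root on the outgroup when its genes are monophyletic, else midpoint.

    Outgroup monophyly is tested on the unrooted tree (the outgroup tip set
    must be one side of some branch; a single outgroup tip always is).
    Midpoint ties resolve to the lexicographically smallest tip pair.
    """
    tips = tree.tips()
    og = frozenset(t.name for t in tips if t.species == outgroup_species)
    all_tips = frozenset(t.name for t in tips)
    if og and og != all_tips:
        # find an edge whose below-set equals the outgroup set or its complement
        for node in tree.postorder():
            if node is tree:
                continue
            below = frozenset(node.tip_names())
            if below == og or (all_tips - below) == og:
                rooted = _root_on_edge(tree, node, node.parent, node.length / 2.0)
                # orient so the outgroup child is listed second
                if frozenset(rooted.children[0].tip_names()) == og:
                    rooted.children.reverse()
                return rooted
    # midpoint rooting
    paths = _tip_paths(tree)
    # deterministic: among max-distance pairs take lexicographically smallest
    dmax = max(d for d, _p in paths.values())
    candidates = sorted(
        tuple(sorted(k)) for k, (d, _p) in paths.items() if abs(d - dmax) < 1e-12
    )
    t1, t2 = candidates[0]
    d, path = paths[(t1, t2)] if (t1, t2) in paths else paths[(t2, t1)]
    half = d / 2.0
    acc = 0.0
    for frm, to, ln in path:
        if acc + ln >= half - 1e-12:
            off = half - acc
            # edge between frm and to; identify child/parent orientation
            if to.parent is frm:
                return _root_on_edge(tree, to, frm, ln - off)
            return _root_on_edge(tree, frm, to, off)
        acc += ln
    # degenerate (zero-length tree): root on the first tip edge
    t = tree.tips()[0]
    return _root_on_edge(tree, t, t.parent, t.length / 2.0)


# ---------------------------------------------------------------------------
# Reconciliation


def classify_nodes(gene_tree: GeneTreeNode, species_tree: SpeciesTree) -> GeneTreeNode:
    """LCA-map every node and label internal nodes.

    duplication: the two child clades share at least one species;
    speciation: no shared species and the node's map is a strict ancestor of
    both children's maps; dubious: no shared species but incongruent.
    """
    for node in gene_tree.postorder():
        if node.is_tip:
            sp = node.species
            if sp is None:
                raise ValueError(f"tip {node.name!r} has no species label")
            try:
                node.species_node = species_tree.tip_ids[sp]
            except KeyError:
                raise KeyError(f"species {sp!r} missing from the species tree")
            node._species_set = frozenset([sp])
            continue
        sets = [c._species_set for c in node.children]
        union = frozenset().union(*sets)
        node._species_set = union
        node.species_node = species_tree.mrca(union)
        shared = any(
            s1 & s2
            for s1, s2 in itertools.combinations(sets, 2)
        )
        if shared:
            node.label = "duplication"
        elif all(
            species_tree.is_strict_ancestor(node.species_node, c.species_node)
            for c in node.children
        ):
            node.label = "speciation"
        else:
            node.label = "dubious"
    return gene_tree


# ---------------------------------------------------------------------------
# Placement


@dataclass
class Placement:
    """An anchor pair's duplication interval on the species tree."""

    gene_a: str
    gene_b: str
    family_id: str
    placed: bool
    lower_node: Optional[int] = None
    upper_node: Optional[int] = None  # None with placed=True => root-open interval
    branch_path: List[Tuple[int, int]] = field(default_factory=list)
    assigned_branch: Optional[Tuple[int, int]] = None
    support: float = 0.0
    dubious_skipped: int = 0
    reason: str = ""

    @property
    def unbounded(self) -> bool:
        return self.placed and self.upper_node is None


def _node_support(node: GeneTreeNode) -> float:
    if node.support is not None:
        return node.support
    if node.parent is None and node.children:
        # the root's two child branches are the same unrooted bipartition
        sup = node.children[0].support
        if sup is not None:
            return sup
    return 0.0


def place_anchor(
    anchor: Tuple[str, str],
    gene_tree: GeneTreeNode,
    species_tree: SpeciesTree,
    family_id: str = "",
) -> Placement:
    """Circumscribe one anchor pair's duplication on the species tree.

    The pair must coalesce at a duplication node (else it is reported
    unplaced); tracing toward the speciation upper bound continues past
    dubious nodes, counting them.
    """
    a, b = anchor
    names = set(gene_tree.tip_names())
    if a not in names or b not in names:
        return Placement(a, b, family_id, placed=False, reason="gene missing from tree")
    node = gene_tree.mrca(a, b)
    if node.label != "duplication":
        return Placement(
            a, b, family_id, placed=False,
            reason=f"coalescent node is {node.label or 'unlabelled'}",
        )
    support = _node_support(node)
    lower = node.species_node
    p = node.parent
    skipped = 0
    while p is not None and p.label != "speciation":
        if p.label == "dubious":
            skipped += 1
        p = p.parent
    if p is None:
        return Placement(
            a, b, family_id, placed=True, lower_node=lower, upper_node=None,
            support=support, dubious_skipped=skipped,
        )
    upper = p.species_node
    path = species_tree.path_up(lower, upper)
    assigned = path[0] if len(path) == 1 else None
    return Placement(
        a, b, family_id, placed=True, lower_node=lower, upper_node=upper,
        branch_path=path, assigned_branch=assigned, support=support,
        dubious_skipped=skipped,
    )


def count_events_per_branch(
    placements: Iterable[Placement],
    support_thresholds: Sequence[int] = (50, 80),
) -> Dict[int, Dict[Tuple[int, int], Dict[str, object]]]:
    """Per-branch counts of qualifying single-branch placements.

    For each threshold t and species-tree branch: the number of distinct
    anchor pairs with support >= t assigned to the branch, the number of
    distinct gene families contributing them, and a per-species breakdown
    (species inferred from the anchor pair's gene-id prefix before '_').
    """
    out: Dict[int, Dict[Tuple[int, int], Dict[str, object]]] = {}
    placements = list(placements)
    for t in support_thresholds:
        per_branch: Dict[Tuple[int, int], Dict[str, object]] = {}
        for p in placements:
            if not p.placed or p.assigned_branch is None or p.support < t:
                continue
            rec = per_branch.setdefault(
                p.assigned_branch,
                {"anchor_pairs": set(), "families": set(), "by_species": defaultdict(set)},
            )
            pair = tuple(sorted((p.gene_a, p.gene_b)))
            rec["anchor_pairs"].add(pair)
            rec["families"].add(p.family_id)
            sp = p.gene_a.split("_")[0]
            rec["by_species"][sp].add(pair)
        out[t] = {
            br: {
                "anchor_pairs": len(rec["anchor_pairs"]),
                "families": len(rec["families"]),
                "by_species": {sp: len(v) for sp, v in sorted(rec["by_species"].items())},
            }
            for br, rec in per_branch.items()
        }
    return out


def placements_to_records(
    placements: Iterable[Placement], species_tree: SpeciesTree
) -> List[dict]:
    """TSV-ready placement rows (feed to ``wgdkit.io.write_tsv``)."""
    records = []
    for p in placements:
        records.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "family": p.family_id,
                "placed": p.placed,
                "lower_node": p.lower_node,
                "upper_node": p.upper_node,
                "assigned_branch": (
                    species_tree.branch_name(p.assigned_branch)
                    if p.assigned_branch is not None
                    else ("unbounded" if p.unbounded else "")
                ),
                "support": p.support,
                "dubious_skipped": p.dubious_skipped,
                "reason": p.reason,
            }
        )
    return records


# ---------------------------------------------------------------------------
# Orchestration


def build_gene_tree(
    family: GeneFamily,
    cds: CodingSequenceSet,
    outgroup_species: str,
    B: int = 200,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GeneTreeNode:
    """NJ + bootstrap + rooting + species labelling for one family."""
    members = sorted(m for m in family.members if m in cds)
    if len(members) < 3:
        raise ValueError("need at least 3 genes for a gene tree")
    X = _aa_matrix(members, cds)
    tree = nj_tree(poisson_distance_matrix(X), members)
    tree = bootstrap_support(tree, X, members, B=B, rng=rng, seed=seed)
    for tip in tree.tips():
        tip.species = family.species[tip.name]
    rooted = root_gene_tree(tree, outgroup_species)
    n_tips = len(members)
    for node in rooted.postorder():
        if node.is_tip or node is rooted:
            continue
        if node.support is None:
            below = len(node.tip_names())
            # a trivial unrooted split (pendant edge) is in every replicate
            if min(below, n_tips - below) <= 1:
                node.support = 100.0
    for tip in rooted.tips():
        tip.species = family.species[tip.name]
    return rooted


def place_families(
    families: Sequence[GeneFamily],
    family_anchors: Dict[str, List[Tuple[str, str]]],
    cds: CodingSequenceSet,
    species_tree: SpeciesTree,
    outgroup_species: str,
    B: int = 200,
    seed: Optional[int] = None,
) -> List[Placement]:
    """Build, root and classify a gene tree per family, then place every
    anchor pair it contains."""
    rng = np.random.default_rng(seed)
    placements: List[Placement] = []
    for fam in families:
        anchors = family_anchors.get(fam.family_id, [])
        if not anchors:
            continue
        try:
            tree = build_gene_tree(fam, cds, outgroup_species, B=B, rng=rng)
        except ValueError as exc:
            for a, b in anchors:
                placements.append(
                    Placement(a, b, fam.family_id, placed=False, reason=str(exc))
                )
            continue
        classify_nodes(tree, species_tree)
        for a, b in anchors:
            placements.append(place_anchor((a, b), tree, species_tree, fam.family_id))
    return placements
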