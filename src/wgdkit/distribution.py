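"""Node-weighted Ks age distributions of a paranome, and KDE peak dating.

A gene family of n members yields n(n-1)/2 pairwise Ks estimates but only
n-1 retained duplication events, so raw pairwise distributions over-count
large families.  The correction implemented here follows the standard
recipe: families are connected components of the thresholded similarity
graph, cut into subfamilies whose pairwise Ks never exceeds a ceiling
(default 5), a tree is built per subfamily, and for each duplication node
with child clades L and R all m = |L|*|R| cross-clade pairs enter the
distribution with weight 1/m — every duplication event carries total mass
one, and a subfamily of n members carries mass n-1.

Peaks are located by weighted Gaussian KDE (Silverman bandwidth, fixed grid
of step 0.01 within the data range) and dated with a bootstrap percentile
confidence interval over peak locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from .ks import KsResult, encode_cds, ks_pair_encoded
from .model import (
    CodingSequenceSet,
    GeneFamily,
    HomologyEdge,
    KsDistribution,
    PipelineConfig,
    WeightedKsEntry,
)

__all__ = [
    "build_families",
    "pairwise_ks",
    "split_subfamilies",
    "SubfamilyTree",
    "subfamily_tree",
    "weight_node_ks",
    "paranome_distribution",
    "pairs_ks_distribution",
    "kde_peak",
    "kde_peaks",
    "bootstrap_peak_ci",
    "select_window",
]

_BIG = 1.0e12  # stands for "farther than any cut" in linkage inputs


# ---------------------------------------------------------------------------
# Families


def build_families(
    edges: Iterable[HomologyEdge],
    evalue_cutoff: Optional[float] = None,
    species_of: Optional[Callable[[str], str]] = None,
) -> List[GeneFamily]:
    """Gene families as connected components of the similarity graph.

    Singletons are discarded.  Family ids are deterministic: families are
    sorted by their lexicographically smallest member.
    """
    g = nx.Graph()
    for e in edges:
        if evalue_cutoff is not None and e.evalue > evalue_cutoff:
            continue
        if e.gene_a == e.gene_b:
            continue
        g.add_edge(e.gene_a, e.gene_b)
    comps = sorted((sorted(c) for c in nx.connected_components(g) if len(c) >= 2))
    out = []
    for i, members in enumerate(comps):
        fam = GeneFamily(family_id=f"fam{i:05d}", members=members)
        if species_of is not None:
            fam.species = {m: species_of(m) for m in members}
        out.append(fam)
    return out


def pairwise_ks(
    members: Sequence[str], cds: CodingSequenceSet
) -> Dict[Tuple[str, str], KsResult]:
    """All pairwise NG86 results within a member list (keys sorted pairs)."""
    enc = {m: encode_cds(cds[m]) for m in members if m in cds}
    out: Dict[Tuple[str, str], KsResult] = {}
    ms = sorted(enc)
    for i, a in enumerate(ms):
        for b in ms[i + 1 :]:
            out[(a, b)] = ks_pair_encoded(enc[a], enc[b])
    return out


def _ks_value(ks_matrix: Dict[Tuple[str, str], KsResult], a: str, b: str) -> float:
    r = ks_matrix[(a, b) if a < b else (b, a)]
    return r.ks


def _condensed(members: Sequence[str], ks_matrix, cap: float = _BIG) -> np.ndarray:
    n = len(members)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _ks_value(ks_matrix, members[i], members[j])
            if not math.isfinite(v):
                v = cap
            d[i, j] = d[j, i] = v
    return squareform(d, checks=False)


def split_subfamilies(
    members: Sequence[str],
    ks_matrix: Dict[Tuple[str, str], KsResult],
    max_ks: float = 5.0,
    method: str = "complete",
) -> List[List[str]]:
    """Complete-linkage cut: within every subfamily all pairwise Ks <= max_ks.

    Saturated or undefined pairs are treated as exceeding the ceiling.
    Members are pre-sorted so the partition is deterministic.  The default
    reads the ceiling strictly (all pairwise Ks within a subfamily comply);
    ``method="single"`` gives the looser chained clustering.
    """
    if method not in ("complete", "single"):
        raise ValueError("method must be 'complete' or 'single'")
    members = sorted(members)
    if len(members) == 1:
        return [list(members)]
    z = linkage(_condensed(members, ks_matrix), method=method)
    labels = fcluster(z, t=max_ks, criterion="distance")
    groups: Dict[int, List[str]] = {}
    for m, lab in zip(members, labels):
        groups.setdefault(int(lab), []).append(m)
    return sorted(groups.values())


# ---------------------------------------------------------------------------
# Subfamily trees and node weighting


@dataclass
class SubfamilyTree:
    """Average-linkage (UPGMA) tree over one subfamily.

    ``height`` of an internal node is half the linkage Ks (ultrametric node
    age); leaves have height 0.  Used only to group pairs per duplication
    node for the 1/m weighting.
    """

    node_id: str
    height: float
    children: List["SubfamilyTree"] = field(default_factory=list)
    leaf: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.leaf]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def internal_nodes(self) -> List["SubfamilyTree"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


def subfamily_tree(
    members: Sequence[str],
    ks_matrix: Dict[Tuple[str, str], KsResult],
    prefix: str = "sub",
    method: str = "upgma",
) -> SubfamilyTree:
    """Tree over one subfamily, used to group pairs per duplication node.

    Default is UPGMA (average linkage) on the pairwise Ks distances —
    adequate for an approximately ultrametric paranome and deterministic.
    ``method="nj"`` is the fallback for strongly rate-heterogeneous
    subfamilies: neighbor joining followed by midpoint rooting.
    """
    members = sorted(members)
    if len(members) < 2:
        raise ValueError("subfamily_tree needs at least 2 members")
    if method == "nj":
        return _nj_subfamily_tree(members, ks_matrix, prefix)
    if method != "upgma":
        raise ValueError("method must be 'upgma' or 'nj'")
    z = linkage(_condensed(members, ks_matrix), method="average")
    nodes: Dict[int, SubfamilyTree] = {
        i: SubfamilyTree(node_id=f"{prefix}:leaf:{m}", height=0.0, leaf=m)
        for i, m in enumerate(members)
    }
    n = len(members)
    for k, (i, j, dist, _cnt) in enumerate(z):
        nodes[n + k] = SubfamilyTree(
            node_id=f"{prefix}:n{k}",
            height=float(dist) / 2.0,
            children=[nodes[int(i)], nodes[int(j)]],
        )
    return nodes[n + len(z) - 1]


def _nj_subfamily_tree(
    members: Sequence[str], ks_matrix, prefix: str
) -> SubfamilyTree:
    from .placement import nj_tree, root_gene_tree

    if len(members) == 2:
        return subfamily_tree(members, ks_matrix, prefix=prefix, method="upgma")
    d = squareform(_condensed(members, ks_matrix), checks=False)
    rooted = root_gene_tree(nj_tree(d, members), outgroup_species="__none__")

    counter = [0]

    def convert(node) -> SubfamilyTree:
        if node.is_tip:
            return SubfamilyTree(node_id=f"{prefix}:leaf:{node.name}", height=0.0, leaf=node.name)
        children = [convert(c) for c in node.children]
        height = max(c.height + gc.length for c, gc in zip(children, node.children))
        k = counter[0]
        counter[0] += 1
        return SubfamilyTree(node_id=f"{prefix}:n{k}", height=height, children=children)

    return convert(rooted)


def weight_node_ks(
    tree: SubfamilyTree, ks_matrix: Dict[Tuple[str, str], KsResult]
) -> List[WeightedKsEntry]:
    """1/m-weighted entries for every duplication node of a subfamily tree.

    For each internal node with child clades L, R, all |L|*|R| cross pairs
    enter with weight 1/(|L|*|R|): per-node mass is exactly 1 and a
    subfamily of n leaves emits n(n-1)/2 entries of total mass n-1.
    """
    entries: List[WeightedKsEntry] = []
    for node in tree.internal_nodes():
        left, right = node.children[0].leaves(), node.children[1].leaves()
        m = len(left) * len(right)
        w = 1.0 / m
        for a in left:
            for b in right:
                ga, gb = (a, b) if a < b else (b, a)
                entries.append(
                    WeightedKsEntry(
                        gene_a=ga,
                        gene_b=gb,
                        ks=_ks_value(ks_matrix, ga, gb),
                        weight=w,
                        node_id=node.node_id,
                        m=m,
                    )
                )
    return entries


def paranome_distribution(
    cds: CodingSequenceSet,
    edges: Iterable[HomologyEdge],
    config: Optional[PipelineConfig] = None,
) -> KsDistribution:
    """Full redundancy-corrected Ks age distribution of one paranome.

    Pipeline: connected-component families at the paranome E-value cutoff ->
    pairwise NG86 Ks -> complete-linkage subfamilies (Ks <= ceiling) ->
    UPGMA subfamily trees -> 1/m node weighting.
    """
    cfg = config or PipelineConfig()
    families = build_families(edges, evalue_cutoff=cfg.paranome_evalue_cutoff)
    entries: List[WeightedKsEntry] = []
    for fam in families:
        members = [m for m in fam.members if m in cds]
        if len(members) < 2:
            continue
        km = pairwise_ks(members, cds)
        for si, sub in enumerate(split_subfamilies(members, km, cfg.subfamily_max_ks)):
            if len(sub) < 2:
                continue
            tree = subfamily_tree(sub, km, prefix=f"{fam.family_id}.s{si}")
            entries.extend(weight_node_ks(tree, km))
    return KsDistribution(entries=entries, source="paranome")


def pairs_ks_distribution(
    pairs: Iterable[Tuple[str, str]],
    cds: CodingSequenceSet,
    source: str = "anchors",
) -> KsDistribution:
    """Unweighted Ks distribution over explicit gene pairs (anchors/orthologs).

    Saturated or undefined pairs are excluded and counted; pairs with a
    missing sequence are skipped the same way.
    """
    entries: List[WeightedKsEntry] = []
    excluded = 0
    for a, b in pairs:
        if a not in cds or b not in cds:
            excluded += 1
            continue
        r = ks_pair_encoded(encode_cds(cds[a]), encode_cds(cds[b]))
        if not math.isfinite(r.ks) or r.saturated:
            excluded += 1
            continue
        ga, gb = (a, b) if a < b else (b, a)
        entries.append(
            WeightedKsEntry(gene_a=ga, gene_b=gb, ks=r.ks, weight=1.0, node_id="", m=1)
        )
    return KsDistribution(entries=entries, source=source, excluded_saturated=excluded)


# ---------------------------------------------------------------------------
# KDE peaks


def _as_arrays(values, weights):
    v = np.asarray(list(values), dtype=float)
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(list(weights), dtype=float)
    keep = np.isfinite(v)
    return v[keep], w[keep]


def _grid(v: np.ndarray, step: float) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    return np.arange(lo, hi + step / 2, step)


def _kde_density(v, w, bandwidth, grid):
    kde = gaussian_kde(v, weights=w, bw_method=bandwidth)
    return kde(grid)


def kde_peaks(
    values,
    weights=None,
    bandwidth: str = "silverman",
    grid_step: float = 0.01,
    min_values: int = 10,
) -> List[Tuple[float, float]]:
    """All local maxima of the weighted KDE, as (location, density),
    ordered by decreasing density (global peak first)."""
    v, w = _as_arrays(values, weights)
    if len(v) < min_values:
        raise ValueError(
            f"need at least {min_values} finite Ks values for peak finding "
            f"(got {len(v)}); provide more data"
        )
    if np.ptp(v) < grid_step:  # degenerate: effectively a point mass
        return [(float(np.average(v, weights=w)), math.inf)]
    grid = _grid(v, grid_step)
    dens = _kde_density(v, w, bandwidth, grid)
    peaks = []
    for i in range(len(grid)):
        left = dens[i - 1] if i > 0 else -math.inf
        right = dens[i + 1] if i < len(grid) - 1 else -math.inf
        if dens[i] >= left and dens[i] >= right:
            peaks.append((float(grid[i]), float(dens[i])))
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks


def kde_peak(values, weights=None, bandwidth: str = "silverman", grid_step: float = 0.01) -> float:
    """Location of the global mode of the weighted KDE (fixed 0.01 grid)."""
    return kde_peaks(values, weights, bandwidth, grid_step)[0][0]


def bootstrap_peak_ci(
    values,
    weights=None,
    B: int = 200,
    coverage: float = 0.90,
    bandwidth: str = "silverman",
    grid_step: float = 0.01,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float, float]:
    """(peak, lo, hi): KDE peak with a bootstrap percentile interval.

    Each resample draws n atoms with probability proportional to their
    weights; the peak of each resample's KDE is recorded and the interval is
    the (1-coverage)/2 .. 1-(1-coverage)/2 percentile range.  Deterministic
    given the seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    v, w = _as_arrays(values, weights)
    if len(v) < 10:
        raise ValueError("need at least 10 finite Ks values; provide more data")
    rng = rng if rng is not None else np.random.default_rng(seed)
    peak = kde_peak(v, w, bandwidth, grid_step)
    p = w / w.sum()
    boots = np.empty(B)
    n = len(v)
    for b in range(B):
        idx = rng.choice(n, size=n, replace=True, p=p)
        vb = v[idx]
        if np.ptp(vb) < grid_step:
            boots[b] = float(vb.mean())
            continue
        grid = _grid(vb, grid_step)
        dens = _kde_density(vb, None, bandwidth, grid)
        boots[b] = float(grid[int(np.argmax(dens))])
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return peak, float(lo), float(hi)


def distribution_to_records(dist: KsDistribution) -> List[dict]:
    """TSV-ready rows of a Ks distribution (feed to ``wgdkit.io.write_tsv``)."""
    return [
        {
            "gene_a": e.gene_a,
            "gene_b": e.gene_b,
            "ks": e.ks,
            "weight": e.weight,
            "node_id": e.node_id,
            "m": e.m,
        }
        for e in dist.entries
    ]


def select_window(entries: Iterable[WeightedKsEntry], lo: float, hi: float) -> List[WeightedKsEntry]:
    """Keep entries with lo <= ks <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError("window lo must be < hi")
    return [e for e in entries if lo <= e.ks <= hi]
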