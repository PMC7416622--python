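"""Co-linear (syntenic) segment detection, merging, and duplication depth.

Anchor pairs — homologous genes sitting inside a run of conserved gene order
— are the high-confidence remnants of large-scale duplications.  Detection
works on gene ranks only: weak homology matches are removed with a c-score
filter, remaining matches on each scaffold pair are chained with a sparse
dynamic program (strictly monotone in both rank coordinates, bounded rank
gaps), overlapping segments are connected into broader regions, and the
number of segments covering each rank gives the duplication-depth profile.

The chainer replaces a profile-search synteny tool with an explicit,
oracle-checkable dynamic program; its defaults (max rank gap 25, match
score +10, gap penalty -1 per skipped rank) are chosen to detect segments of
five or more anchors through moderate post-WGD gene loss, and are all
exposed.  Depth beyond pairwise segments is obtained only through
overlapping pairwise segments (no recursive profile search).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .model import HomologyEdge, SpeciesGenome

__all__ = [
    "MatchPoint",
    "CollinearSegment",
    "Region",
    "DepthProfile",
    "cscore_filter",
    "build_match_points",
    "chain_matches",
    "collinear_segments",
    "anchor_pairs",
    "merge_segments",
    "duplication_depth",
    "pattern_summary",
    "PatternReport",
]


@dataclass(frozen=True)
class MatchPoint:
    """One homology match projected onto gene-rank coordinates."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    strand_a: str = "+"
    strand_b: str = "+"


@dataclass
class CollinearSegment:
    """A chained run of anchor pairs on one scaffold pair.

    rank_a is strictly increasing along the segment; rank_b strictly
    increasing (forward) or strictly decreasing (inverted).
    """

    scaffold_a: str
    scaffold_b: str
    anchors: List[MatchPoint]
    direction: str  # "forward" | "inverted"
    score: float

    def __post_init__(self):
        ra = [m.rank_a for m in self.anchors]
        rb = [m.rank_b for m in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError("segment not strictly increasing in rank_a")
        inc = all(y > x for x, y in zip(rb, rb[1:]))
        dec = all(y < x for x, y in zip(rb, rb[1:]))
        if not (inc or dec):
            raise ValueError("segment not strictly monotone in rank_b")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def interval_a(self) -> Tuple[int, int]:
        ra = [m.rank_a for m in self.anchors]
        return min(ra), max(ra)

    @property
    def interval_b(self) -> Tuple[int, int]:
        rb = [m.rank_b for m in self.anchors]
        return min(rb), max(rb)


@dataclass
class Region:
    """A broader region: union of overlapping segment intervals on one scaffold."""

    scaffold: str
    start: int
    end: int
    segments: List[CollinearSegment] = field(default_factory=list)


@dataclass
class DepthProfile:
    """Per-rank duplication depth of one scaffold.

    ``depth[r]`` counts the co-linear segment intervals covering rank r
    (recomputable by brute force).  ``multiplicity`` adds the region itself
    as one copy (depth + 1 inside covered regions): after one WGD with full
    retention a duplicated region has depth 1 and multiplicity 2; after two
    rounds, depth 3 and multiplicity 4 — the genomic copy number.
    """

    scaffold: str
    depth: np.ndarray

    @property
    def multiplicity(self) -> np.ndarray:
        return np.where(self.depth > 0, self.depth + 1, 0)


# ---------------------------------------------------------------------------
# c-score filter


def cscore_filter(
    edges: Iterable[HomologyEdge], cscore_min: float = 0.5
) -> List[HomologyEdge]:
    """Drop weak matches: keep edges whose bit-score reaches ``cscore_min``
    of the best bit-score involving either gene.

    cscore(a,b) = bitscore(a,b) / max(best(a), best(b)); the filled value is
    stored on the surviving edges.
    """
    edges = list(edges)
    best: Dict[str, float] = defaultdict(float)
    for e in edges:
        best[e.gene_a] = max(best[e.gene_a], e.bitscore)
        best[e.gene_b] = max(best[e.gene_b], e.bitscore)
    kept = []
    for e in edges:
        denom = max(best[e.gene_a], best[e.gene_b])
        e.cscore = e.bitscore / denom if denom > 0 else 0.0
        if e.cscore >= cscore_min:
            kept.append(e)
    return kept


# ---------------------------------------------------------------------------
# Match points


def build_match_points(
    genome_a: SpeciesGenome,
    genome_b: SpeciesGenome,
    edges: Iterable[HomologyEdge],
) -> Dict[Tuple[str, str], List[MatchPoint]]:
    """Project homology edges onto rank coordinates, per scaffold pair.

    In a self-comparison (same species on both sides) the identity diagonal
    is masked and each unordered gene pair is kept once, oriented so that
    (scaffold_a, rank_a) <= (scaffold_b, rank_b).
    """
    self_cmp = genome_a.species_id == genome_b.species_id
    seen: set = set()
    out: Dict[Tuple[str, str], List[MatchPoint]] = defaultdict(list)
    strand = {
        g.gene_id: g.strand
        for gen in ((genome_a, genome_b) if not self_cmp else (genome_a,))
        for sc in gen.scaffolds.values()
        for g in sc
    }
    for e in edges:
        a, b = e.gene_a, e.gene_b
        if a == b:
            continue
        if a not in genome_a or b not in genome_b:
            if self_cmp:
                continue
            # tolerate edges written in the other direction
            if b in genome_a and a in genome_b:
                a, b = b, a
            else:
                continue
        sa, ra = genome_a.locate(a)
        sb, rb = genome_b.locate(b)
        if self_cmp:
            if (sb, rb, b) < (sa, ra, a):
                a, b, sa, sb, ra, rb = b, a, sb, sa, rb, ra
            key = (a, b)
            if key in seen:
                continue
            seen.add(key)
        else:
            key = (a, b)
            if key in seen:
                continue
            seen.add(key)
        out[(sa, sb)].append(
            MatchPoint(
                gene_a=a, gene_b=b, rank_a=ra, rank_b=rb,
                strand_a=strand.get(a, "+"), strand_b=strand.get(b, "+"),
            )
        )
    return dict(out)


# ---------------------------------------------------------------------------
# Chaining


def _gap_cost(dp_a: int, dp_b: int) -> int:
    return (dp_a - 1) + (dp_b - 1)


def _best_chain(
    matches: List[MatchPoint],
    direction: int,
    max_rank_gap: int,
    gap_penalty: float,
    match_score: float,
) -> Tuple[float, List[int]]:
    """Best-scoring monotone chain in one direction.

    Returns (score, indices into ``matches``).  Ties are broken toward the
    lexicographically smallest (rank_a, rank_b) sequence; a chain never
    extends when the extension does not strictly improve its score.
    """
    order = sorted(range(len(matches)), key=lambda i: (matches[i].rank_a, matches[i].rank_b))
    pts = [(matches[i].rank_a, matches[i].rank_b) for i in order]
    n = len(pts)
    if n < 2:
        return 0.0, []
    # f1[i]: best score over chains of length >= 1 starting at i (a chain
    # stops rather than take a non-improving extension; on an exact tie the
    # shorter chain is the lexicographically smaller sequence).
    f1 = [match_score] * n
    nxt: List[Optional[int]] = [None] * n
    # first[i]: best (continuation value, successor) over ALL valid first
    # steps, even score-decreasing ones — needed for chains forced to have
    # length >= 2.
    first: List[Optional[Tuple[float, int]]] = [None] * n
    for ii in range(n - 1, -1, -1):
        a0, b0 = pts[ii]
        for jj in range(ii + 1, n):
            a1, b1 = pts[jj]
            da = a1 - a0
            if da > max_rank_gap:
                break
            db = (b1 - b0) * direction
            if da <= 0 or db <= 0 or db > max_rank_gap:
                continue
            cont = f1[jj] + gap_penalty * _gap_cost(da, db)
            if first[ii] is None or cont > first[ii][0]:
                first[ii] = (cont, jj)
        if first[ii] is not None and first[ii][0] > 0:
            f1[ii] = match_score + first[ii][0]
            nxt[ii] = first[ii][1]
    starts = [i for i in range(n) if first[i] is not None]
    if not starts:
        return 0.0, []
    best_score = max(match_score + first[i][0] for i in starts)
    if best_score <= 0:  # only positive-scoring chains are reportable
        return 0.0, []
    start = min(
        (i for i in starts if match_score + first[i][0] == best_score),
        key=lambda i: pts[i],
    )
    chain = [order[start]]
    cur = first[start][1]
    while cur is not None:
        chain.append(order[cur])
        cur = nxt[cur]
    return best_score, chain


def chain_matches(
    matches: Sequence[MatchPoint],
    scaffold_a: str = "A",
    scaffold_b: str = "B",
    max_rank_gap: int = 25,
    gap_penalty: float = -1.0,
    match_score: float = 10.0,
    min_anchor_pairs: int = 5,
) -> List[CollinearSegment]:
    """Chain matches on one scaffold pair into co-linear segments.

    Segments are maximal-scoring chains under a sparse dynamic program: a
    chain step must advance both rank coordinates by 1..max_rank_gap with a
    consistent direction; score = n * match_score + gap_penalty * (skipped
    ranks).  Chains are extracted best-score first (ties toward the leftmost
    rank_a), each match is used at most once, and chains with fewer than
    ``min_anchor_pairs`` anchors are discarded.
    """
    remaining = list(dict.fromkeys(matches))  # de-duplicate, keep order
    segments: List[CollinearSegment] = []
    while len(remaining) >= 2:
        candidates = []
        for direction, name in ((1, "forward"), (-1, "inverted")):
            score, chain = _best_chain(
                remaining, direction, max_rank_gap, gap_penalty, match_score
            )
            if len(chain) >= 2:
                candidates.append((score, name, chain))
        if not candidates:
            break
        candidates.sort(
            key=lambda c: (-c[0], [(remaining[i].rank_a, remaining[i].rank_b) for i in c[2]])
        )
        score, name, chain = candidates[0]
        pts = [remaining[i] for i in chain]
        segments.append(
            CollinearSegment(
                scaffold_a=scaffold_a,
                scaffold_b=scaffold_b,
                anchors=pts,
                direction=name,
                score=score,
            )
        )
        used = set(chain)
        remaining = [m for i, m in enumerate(remaining) if i not in used]
    return [s for s in segments if s.n_anchors >= min_anchor_pairs]


def collinear_segments(
    genome_a: SpeciesGenome,
    genome_b: SpeciesGenome,
    edges: Iterable[HomologyEdge],
    cscore_min: float = 0.5,
    max_rank_gap: int = 25,
    gap_penalty: float = -1.0,
    match_score: float = 10.0,
    min_anchor_pairs: int = 5,
) -> List[CollinearSegment]:
    """End-to-end anchor detection between (or within) genomes.

    Applies the c-score filter, projects matches to rank coordinates per
    scaffold pair, and chains each scaffold pair independently.
    """
    strong = cscore_filter(edges, cscore_min=cscore_min)
    points = build_match_points(genome_a, genome_b, strong)
    segments: List[CollinearSegment] = []
    for (sa, sb) in sorted(points):
        segments.extend(
            chain_matches(
                points[(sa, sb)],
                scaffold_a=sa,
                scaffold_b=sb,
                max_rank_gap=max_rank_gap,
                gap_penalty=gap_penalty,
                match_score=match_score,
                min_anchor_pairs=min_anchor_pairs,
            )
        )
    return segments


def segments_to_records(segments: Sequence[CollinearSegment]) -> List[dict]:
    """Flatten segments to TSV-ready anchor records (dot-plot export).

    One record per anchor pair, labelled with its segment; feed to
    ``wgdkit.io.write_tsv``.
    """
    records = []
    for k, s in enumerate(segments):
        for m in s.anchors:
            records.append(
                {
                    "segment_id": f"seg{k:04d}",
                    "scaffold_a": s.scaffold_a,
                    "scaffold_b": s.scaffold_b,
                    "direction": s.direction,
                    "gene_a": m.gene_a,
                    "gene_b": m.gene_b,
                    "rank_a": m.rank_a,
                    "rank_b": m.rank_b,
                }
            )
    return records


def anchor_pairs(segments: Iterable[CollinearSegment]) -> List[Tuple[str, str]]:
    """Unique unordered anchor gene pairs across segments (sorted)."""
    pairs = {
        tuple(sorted((m.gene_a, m.gene_b)))
        for s in segments
        for m in s.anchors
    }
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Regions, depth, multiplicity patterns


def _segment_intervals(
    segments: Iterable[CollinearSegment], side: str
) -> Dict[str, List[Tuple[int, int, CollinearSegment]]]:
    out: Dict[str, List[Tuple[int, int, CollinearSegment]]] = defaultdict(list)
    for s in segments:
        if side in ("a", "both"):
            lo, hi = s.interval_a
            out[s.scaffold_a].append((lo, hi, s))
        if side in ("b", "both"):
            lo, hi = s.interval_b
            out[s.scaffold_b].append((lo, hi, s))
    return out


def merge_segments(
    segments: Iterable[CollinearSegment], side: str = "both"
) -> Dict[str, List[Region]]:
    """Union overlapping segment rank-intervals into broader regions.

    Intervals are closed; a shared single rank counts as overlap.  ``side``
    selects which scaffold of each segment contributes ("a", "b", "both" —
    in a self-comparison both sides live on the same genome).
    """
    regions: Dict[str, List[Region]] = {}
    for scaf, ivals in sorted(_segment_intervals(segments, side).items()):
        ivals = sorted(ivals, key=lambda t: (t[0], t[1]))
        merged: List[Region] = []
        for lo, hi, seg in ivals:
            if merged and lo <= merged[-1].end:
                merged[-1].end = max(merged[-1].end, hi)
                merged[-1].segments.append(seg)
            else:
                merged.append(Region(scaffold=scaf, start=lo, end=hi, segments=[seg]))
        regions[scaf] = merged
    return regions


def duplication_depth(
    segments: Iterable[CollinearSegment], scaffold: str, n_ranks: int
) -> DepthProfile:
    """Per-rank count of co-linear segment intervals covering the scaffold."""
    depth = np.zeros(n_ranks, dtype=int)
    for scaf, ivals in _segment_intervals(segments, "both").items():
        if scaf != scaffold:
            continue
        for lo, hi, _seg in ivals:
            depth[lo : hi + 1] += 1
    return DepthProfile(scaffold=scaffold, depth=depth)


@dataclass
class PatternReport:
    """Region-level multiplicity patterns of a cross-genome comparison.

    Each connected component of the region link graph is summarized as
    (number of A regions : number of B regions); ``modal_pattern`` is the
    most frequent such claim (e.g. (4, 1) after two WGDs in A and none in B).
    """

    region_degree_b: Dict[Tuple[str, int], int]  # B region -> #distinct A regions
    region_degree_a: Dict[Tuple[str, int], int]  # A region -> #distinct B regions
    component_patterns: List[Tuple[int, int]]
    modal_pattern: Optional[Tuple[int, int]]


def pattern_summary(
    genome_a: SpeciesGenome,
    genome_b: SpeciesGenome,
    segments: Sequence[CollinearSegment],
) -> PatternReport:
    """a:b multiplicity claims from a cross-genome comparison.

    Regions are formed independently on each genome; two regions are linked
    when a segment contributes an interval to both.  For every region in B
    the number of distinct linked A regions is reported (and vice versa),
    and each connected component yields an (nA : nB) pattern.
    """
    regions_a = merge_segments(segments, side="a")
    regions_b = merge_segments(segments, side="b")

    # map each segment to its region on each side
    seg_to_a: Dict[int, Tuple[str, int]] = {}
    for scaf, regs in regions_a.items():
        for k, r in enumerate(regs):
            for s in r.segments:
                seg_to_a[id(s)] = (scaf, k)
    seg_to_b: Dict[int, Tuple[str, int]] = {}
    for scaf, regs in regions_b.items():
        for k, r in enumerate(regs):
            for s in r.segments:
                seg_to_b[id(s)] = (scaf, k)

    links: set[Tuple[Tuple[str, int], Tuple[str, int]]] = set()
    for s in segments:
        if id(s) in seg_to_a and id(s) in seg_to_b:
            links.add((seg_to_a[id(s)], seg_to_b[id(s)]))

    deg_b: Dict[Tuple[str, int], set] = defaultdict(set)
    deg_a: Dict[Tuple[str, int], set] = defaultdict(set)
    for ra, rb in links:
        deg_b[rb].add(ra)
        deg_a[ra].add(rb)

    g = nx.Graph()
    for ra, rb in links:
        g.add_edge(("A",) + ra, ("B",) + rb)
    patterns = []
    for comp in nx.connected_components(g):
        na = sum(1 for n in comp if n[0] == "A")
        nb = sum(1 for n in comp if n[0] == "B")
        patterns.append((na, nb))
    patterns.sort()
    modal = Counter(patterns).most_common(1)[0][0] if patterns else None
    return PatternReport(
        region_degree_b={k: len(v) for k, v in deg_b.items()},
        region_degree_a={k: len(v) for k, v in deg_a.items()},
        component_patterns=patterns,
        modal_pattern=modal,
    )
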