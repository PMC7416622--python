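"""Independent brute-force oracles used to check wgdkit's implementations.

Everything here is deliberately written from first principles (enumeration,
exhaustive search, naive data structures) and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return "*" if codon in STOPS else str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# NG86


def ng86_sites_oracle(cds: str):
    """Synonymous/nonsynonymous site counts by direct enumeration."""
    S = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = _aa(codon)
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if _aa(mut) == aa and aa != "*":
                    S += 1 / 3
    return S, 3 * (len(cds) // 3) - S


def ng86_diffs_oracle(a: str, b: str):
    """Pathway-averaged difference counts by direct enumeration."""
    Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        positions = [p for p in range(3) if ca[p] != cb[p]]
        if not positions:
            continue
        syn = nsyn = 0.0
        paths = 0
        for order in itertools.permutations(positions):
            cur = ca
            s = n = 0
            ok = True
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if _aa(nxt) == "*" and nxt != cb:
                    ok = False
                    break
                if _aa(nxt) == _aa(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                syn += s
                nsyn += n
                paths += 1
        if paths:
            Sd += syn / paths
            Nd += nsyn / paths
    return Sd, Nd


def ks_oracle(a: str, b: str):
    """Full NG86+JC Ks/Ka for two aligned CDS (no ambiguity handling)."""
    Sa, _ = ng86_sites_oracle(a)
    Sb, _ = ng86_sites_oracle(b)
    S = (Sa + Sb) / 2
    N = 3 * (len(a) // 3) - S
    Sd, Nd = ng86_diffs_oracle(a, b)
    pS, pN = Sd / S, Nd / N

    def jc(p):
        arg = 1 - 4 * p / 3
        return math.inf if arg <= 0 else -0.75 * math.log(arg)

    return jc(pS), jc(pN), pS, pN


# ---------------------------------------------------------------------------
# Chaining


def best_chain_oracle(points, max_gap=25, gap_penalty=-1.0, match_score=10.0):
    """Exhaustive best chain over (rank_a, rank_b) points, both directions.

    Returns (score, chain as list of points); among equal-score chains the
    lexicographically smallest point sequence (Python list order) wins.
    """
    pts = sorted(set(points))
    best = (0.0, [])

    def consider(chain):
        nonlocal best
        score = match_score * len(chain)
        for (a0, b0), (a1, b1) in zip(chain, chain[1:]):
            score += gap_penalty * ((a1 - a0 - 1) + (abs(b1 - b0) - 1))
        cand = (score, chain[:])
        if len(chain) >= 2 and (
            cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1])
        ):
            best = cand

    def extend(chain, direction):
        consider(chain)
        a0, b0 = chain[-1]
        for p in pts:
            a1, b1 = p
            da, db = a1 - a0, (b1 - b0) * direction
            if 0 < da <= max_gap and 0 < db <= max_gap:
                chain.append(p)
                extend(chain, direction)
                chain.pop()

    for p in pts:
        for direction in (1, -1):
            extend([p], direction)
    return best


# ---------------------------------------------------------------------------
# RBH


def rbh_oracle(scores_ab, scores_ba):
    """Brute-force reciprocal best hits.

    scores_* : dict (query, subject) -> (bitscore, evalue), already
    cutoff-filtered.  Best = max bitscore, then min evalue, then smallest id.
    """

    def best(scores):
        out = {}
        for (q, s), (bs, ev) in scores.items():
            key = (-bs, ev, s)
            if q not in out or key < out[q]:
                out[q] = key
        return {q: k[2] for q, k in out.items()}

    ab, ba = best(scores_ab), best(scores_ba)
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


# ---------------------------------------------------------------------------
# Graph / interval helpers


def components_oracle(n_labels, edges):
    """Connected components via naive repeated expansion."""
    comps = []
    seen = set()
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        frontier = {start}
        while frontier:
            nxt = set()
            for x in frontier:
                nxt |= adj.get(x, set())
            frontier = nxt - comp
            comp |= nxt
        seen |= comp
        comps.append(sorted(comp))
    return sorted(comps)


def complete_linkage_oracle(labels, dist, cutoff):
    """Naive agglomerative complete linkage cut at ``cutoff``.

    dist: dict frozenset({a,b}) -> distance.  Repeatedly merges the two
    clusters with the smallest maximum pairwise distance while it is
    <= cutoff.
    """
    clusters = [[l] for l in labels]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    dist[frozenset((a, b))]
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best is None or best[0] > cutoff:
            break
        d, i, j = best
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(sorted(c) for c in clusters)


def interval_union_oracle(intervals):
    """Union of closed integer intervals by per-point membership."""
    if not intervals:
        return []
    lo = min(i[0] for i in intervals)
    hi = max(i[1] for i in intervals)
    covered = [any(a <= x <= b for a, b in intervals) for x in range(lo, hi + 1)]
    out = []
    x = 0
    while x < len(covered):
        if covered[x]:
            start = x
            while x < len(covered) and covered[x]:
                x += 1
            out.append((start + lo, x - 1 + lo))
        else:
            x += 1
    return out


def depth_oracle(intervals, n_ranks):
    """Per-rank coverage count of closed intervals."""
    return [sum(1 for a, b in intervals if a <= r <= b) for r in range(n_ranks)]
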