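"""Pairwise synonymous / nonsynonymous divergence by Nei–Gojobori counting.

Ks (synonymous substitutions per synonymous site) is the age proxy of every
distribution this package builds.  The estimator is the classical NG86
counting method: fractional synonymous site counts per codon, difference
counts averaged over all shortest mutational pathways between two codons
(pathways through a stop codon are excluded from the average), and a
Jukes–Cantor multiple-hit correction,

    Ks = -(3/4) * ln(1 - (4/3) * pS),   pS = Sd / mean(S_a, S_b),

and likewise Ka from pN.  The method is deterministic and exactly checkable
against brute-force pathway enumeration, which is why it is used here; it is
known to mildly underestimate divergence at high Ks relative to
maximum-likelihood codon models, which does not move the location of a Ks
peak at the ages relevant for WGD detection.

Standard genetic code only.  Codons containing an ambiguous base are skipped
pairwise (removed from both sites and differences of the comparison).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "KsResult",
    "ng86_sites",
    "ng86_differences",
    "ks_pair",
    "encode_cds",
    "ks_pair_encoded",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: codon string -> amino acid; '*' marks the three stop codons
CODON_AA: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_AA[_stop] = "*"

ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if CODON_AA[c] != "*"]
_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


def _codon_syn_sites(codon: str) -> float:
    """Fraction of the codon's three sites at which change is synonymous.

    Each position contributes (#synonymous single-base changes)/3; a change
    into a stop codon counts as nonsynonymous.
    """
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_AA[mutant] == aa:  # stop mutants have aa '*', never equal
                s += 1.0 / 3.0
    return s


def _pair_path_counts(ca: str, cb: str) -> Tuple[float, float, bool]:
    """(Sd, Nd, ok) for one codon pair, averaged over unblocked shortest paths."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0, True
    syn_tot = 0.0
    nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diffs):
        cur = ca
        syn = 0
        nsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if CODON_AA[nxt] == "*" and nxt != cb:
                blocked = True  # pathway passes through a stop codon
                break
            if CODON_AA[nxt] == CODON_AA[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if not blocked:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return syn_tot / n_paths, nsyn_tot / n_paths, True


def _build_tables():
    n = len(ALL_CODONS)
    s_sites = np.full(n, np.nan)
    for c in SENSE_CODONS:
        s_sites[_CODON_INDEX[c]] = _codon_syn_sites(c)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    ok = np.zeros((n, n), dtype=bool)
    for ca in SENSE_CODONS:
        ia = _CODON_INDEX[ca]
        for cb in SENSE_CODONS:
            ib = _CODON_INDEX[cb]
            sd[ia, ib], nd[ia, ib], ok[ia, ib] = _pair_path_counts(ca, cb)
    return s_sites, sd, nd, ok


_S_SITES_TABLE, _SD_TABLE, _ND_TABLE, _OK_TABLE = _build_tables()


@dataclass
class KsResult:
    """NG86 divergence estimates for one pair of coding sequences."""

    ks: float
    ka: float
    pS: float
    pN: float
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    saturated: bool
    n_codons: int  # codons actually compared (unambiguous, unblocked)


def _codon_indices(cds: str) -> np.ndarray:
    """Codon index array; -1 marks codons with ambiguous bases."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    arr = np.frombuffer(cds.encode(), dtype="S1")
    idx = np.full(len(cds), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[arr == b.encode()] = i
    cod = idx.reshape(-1, 3)
    out = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    out[(cod < 0).any(axis=1)] = -1
    return out


def encode_cds(cds: str) -> np.ndarray:
    """Encode a CDS as codon indices for the fast pairwise path."""
    codons = _codon_indices(cds)
    for i in codons[codons >= 0]:
        if CODON_AA[ALL_CODONS[i]] == "*":
            raise ValueError("internal stop codon")
    return codons


def ng86_sites(cds: str) -> Tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts of one CDS.

    S + N = 3 * (number of unambiguous codons).
    """
    codons = encode_cds(cds)
    valid = codons[codons >= 0]
    s = float(_S_SITES_TABLE[valid].sum())
    return s, 3.0 * len(valid) - s


def ng86_differences(cds_a: str, cds_b: str) -> Tuple[float, float]:
    """Pathway-averaged synonymous and nonsynonymous difference counts."""
    ia, ib = encode_cds(cds_a), encode_cds(cds_b)
    if len(ia) != len(ib):
        raise ValueError("sequences differ in length")
    mask = (ia >= 0) & (ib >= 0) & _OK_TABLE[ia.clip(0), ib.clip(0)]
    return (
        float(_SD_TABLE[ia[mask], ib[mask]].sum()),
        float(_ND_TABLE[ia[mask], ib[mask]].sum()),
    )


def _jc(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.inf
    return -0.75 * math.log(arg)


def ks_pair_encoded(ia: np.ndarray, ib: np.ndarray) -> KsResult:
    """NG86 Ks/Ka from pre-encoded codon index arrays (pairwise deletion)."""
    if len(ia) != len(ib):
        raise ValueError("sequences differ in length")
    mask = (ia >= 0) & (ib >= 0) & _OK_TABLE[ia.clip(0), ib.clip(0)]
    a, b = ia[mask], ib[mask]
    n_codons = int(mask.sum())
    s_a = float(_S_SITES_TABLE[a].sum())
    s_b = float(_S_SITES_TABLE[b].sum())
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    Sd = float(_SD_TABLE[a, b].sum())
    Nd = float(_ND_TABLE[a, b].sum())
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    ks = _jc(pS) if S > 0 else math.nan
    ka = _jc(pN) if N > 0 else math.nan
    saturated = (not math.isnan(pS) and pS >= 0.75) or (
        not math.isnan(pN) and pN >= 0.75
    )
    return KsResult(
        ks=ks, ka=ka, pS=pS, pN=pN, S_sites=S, N_sites=N, Sd=Sd, Nd=Nd,
        saturated=saturated, n_codons=n_codons,
    )


def ks_pair(cds_a: str, cds_b: str) -> KsResult:
    """NG86 Ks and Ka between two equal-length, in-frame coding sequences.

    Sites are averaged over the two sequences (over compared codons only);
    the Jukes–Cantor correction is applied to both proportions.  The
    ``saturated`` flag marks pS or pN at or beyond the JC ceiling of 3/4,
    in which case the corresponding rate is +inf.
    """
    return ks_pair_encoded(encode_cds(cds_a), encode_cds(cds_b))


def is_synonymous_change(codon: str, pos: int, alt: str) -> Optional[bool]:
    """For the simulator: classify a single-base change.

    Returns True (synonymous), False (nonsynonymous), or None if the mutant
    is a stop codon (such proposals are rejected outright).
    """
    mutant = codon[:pos] + alt + codon[pos + 1 :]
    if CODON_AA[mutant] == "*":
        return None
    return CODON_AA[mutant] == CODON_AA[codon]
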