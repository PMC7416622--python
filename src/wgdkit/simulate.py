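"""Synthetic genome evolution with known WGD ground truth.

The generator emulates exactly the statistical structure the downstream
analysis assumes: gene families descend along a known ultrametric species
tree; a WGD on a chosen branch duplicates every scaffold and each duplicate
gene survives with a retention probability; surviving duplicated gene orders
stay co-linear up to later fractionation and inversions; and codon sequences
accumulate synonymous substitutions so that the pairwise NG86 Ks of two
genes tracks the age of their divergence.

Units.  Species-tree branch lengths are per-lineage Ks (expected synonymous
substitutions per synonymous site along that lineage), so the expected
pairwise Ks of two tips is their path length, i.e. twice the height of
their split on an ultrametric tree.  A WGD event's ``age_ks`` is the
expected *pairwise* Ks between the duplicates it leaves — the quantity on
the x-axis of every Ks distribution — so the event sits at per-lineage
height ``age_ks / 2``.

Sequences evolve without indels, so codon alignment is the identity and no
multiple-sequence alignment stage is needed downstream.  Homology scores
are similarity proxies (bitscore = (1 - protein p-distance) * protein
length), sufficient because the pipeline uses only score rank order, an
E-value cutoff and c-score ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .ks import CODON_AA, SENSE_CODONS, is_synonymous_change, ng86_sites
from .model import CodingSequenceSet, GeneRecord, HomologyEdge, SpeciesGenome
from .tree import SpeciesTree

__all__ = [
    "WgdSpec",
    "SimConfig",
    "SimGene",
    "GroundTruth",
    "TrueEvent",
    "SimResult",
    "simulate_dataset",
    "evolve_sequence",
    "apply_wgd",
    "apply_inversions",
    "write_dataset",
]

_EVALUE_FLOOR = 1e-180


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class WgdSpec:
    """One whole-genome duplication on a species-tree branch.

    ``branch`` names the branch by the species set of the clade below it
    (a single species id or an iterable of ids); ``age_ks`` is the expected
    pairwise Ks between surviving duplicates; each duplicate gene copy is
    kept independently with probability ``retention_prob``.
    """

    branch: Union[str, Sequence[str]]
    age_ks: float
    retention_prob: float

    def species(self) -> Tuple[str, ...]:
        if isinstance(self.branch, str):
            return (self.branch,)
        return tuple(sorted(self.branch))

    def __post_init__(self):
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")
        if self.age_ks < 0:
            raise ValueError("age_ks must be >= 0")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``fractionation_prob`` is a loss rate per redundant gene copy per
    per-lineage Ks unit after a WGD (only genes with >= 2 surviving copies
    in their genome are eligible, emulating biased duplicate loss);
    ``small_scale_dup_rate`` is a tandem duplication rate per gene per
    per-lineage Ks unit; ``omega`` is the dN/dS acceptance probability for
    nonsynonymous proposals.
    """

    species_newick: str
    wgd_events: List[WgdSpec] = field(default_factory=list)
    n_families: int = 500
    genes_per_scaffold: int = 100
    n_scaffolds: Optional[int] = None  # derived from n_families when None
    fractionation_prob: float = 0.05
    n_inversions: int = 2
    cds_codons: int = 300
    omega: float = 0.2
    small_scale_dup_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.cds_codons < 50:
            raise ValueError("cds_codons must be >= 50")
        for name in ("fractionation_prob", "small_scale_dup_rate", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_scaffolds is None:
            self.n_scaffolds = max(1, math.ceil(self.n_families / self.genes_per_scaffold))


# ---------------------------------------------------------------------------
# Sequence evolution


def _evolve(
    parent_cds: str,
    target_ks: float,
    omega: float,
    rng: np.random.Generator,
    max_factor: int = 500,
) -> Tuple[str, bool]:
    """Child sequence and a flag marking an unreachable (capped) target.

    Proposal process: a uniform random site gets a uniform random different
    base; proposals creating an internal stop are rejected; synonymous
    proposals are always accepted, nonsynonymous ones with probability
    ``omega``.  The process stops once the number of accepted synonymous
    substitutions reaches a Poisson-drawn target with mean
    ``target_ks * S_sites(parent)``, so the Jukes–Cantor-corrected NG86 Ks
    between parent and child concentrates around ``target_ks``.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks == 0:
        return parent_cds, False
    s_sites, _ = ng86_sites(parent_cds)
    target = int(rng.poisson(target_ks * s_sites))
    if target == 0:
        return parent_cds, False
    seq = list(parent_cds)
    L = len(seq)
    syn = 0
    proposals = 0
    max_proposals = max(20000, max_factor * L)
    alt_of = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    while syn < target and proposals < max_proposals:
        k = 512
        sites = rng.integers(0, L, k).tolist()
        picks = rng.integers(0, 3, k).tolist()
        draws = rng.random(k).tolist()
        for pos, pick, draw in zip(sites, picks, draws):
            if syn >= target:
                break
            proposals += 1
            ci = pos - pos % 3
            codon = seq[ci] + seq[ci + 1] + seq[ci + 2]
            alt = alt_of[seq[pos]][pick]
            cls = is_synonymous_change(codon, pos - ci, alt)
            if cls is None:
                continue  # would create an internal stop
            if cls:
                seq[pos] = alt
                syn += 1
            elif draw < omega:
                seq[pos] = alt
    return "".join(seq), syn < target


def evolve_sequence(
    parent_cds: str, target_ks: float, omega: float, rng: np.random.Generator
) -> str:
    """Evolve a child CDS to an expected NG86 Ks of ``target_ks`` vs parent."""
    child, _capped = _evolve(parent_cds, target_ks, omega, rng)
    return child


# ---------------------------------------------------------------------------
# Genome state


@dataclass
class SimGene:
    """A gene copy inside the simulator's genome state."""

    lineage: int
    family: int
    seq: str
    strand: str = "+"
    capped: bool = False


GenomeState = List[List[SimGene]]


def apply_wgd(
    scaffolds: GenomeState,
    retention_prob: float,
    rng: np.random.Generator,
    duplicate_fn=None,
) -> GenomeState:
    """Whole-genome duplication: append duplicated scaffolds, then drop each
    duplicate gene independently with probability 1 - retention_prob.

    ``duplicate_fn(gene) -> (copy_kept_in_place, duplicate_copy)`` lets the
    simulator register new genealogy lineages; the default just copies.
    """
    if duplicate_fn is None:
        duplicate_fn = lambda g: (
            g,
            SimGene(lineage=g.lineage, family=g.family, seq=g.seq, strand=g.strand, capped=g.capped),
        )
    new_state: GenomeState = []
    dup_scaffolds: GenomeState = []
    for scaf in scaffolds:
        kept: List[SimGene] = []
        dups: List[SimGene] = []
        for g in scaf:
            c1, c2 = duplicate_fn(g)
            kept.append(c1)
            if rng.random() < retention_prob:
                dups.append(c2)
        new_state.append(kept)
        dup_scaffolds.append(dups)
    return new_state + [d for d in dup_scaffolds]


def apply_inversions(
    scaffolds: GenomeState, n: int, rng: np.random.Generator
) -> GenomeState:
    """Reverse n uniformly chosen contiguous rank intervals, flipping strands."""
    state = [list(s) for s in scaffolds]
    eligible = [i for i, s in enumerate(state) if len(s) >= 2]
    if not eligible:
        return state
    for _ in range(n):
        si = eligible[int(rng.integers(0, len(eligible)))]
        scaf = state[si]
        i, j = sorted(int(x) for x in rng.integers(0, len(scaf), 2))
        window = scaf[i : j + 1][::-1]
        for g in window:
            g.strand = "+" if g.strand == "-" else "-"
        state[si] = scaf[:i] + window + scaf[j + 1 :]
    return state


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class TrueEvent:
    """One simulated WGD with its surviving duplicate (true anchor) pairs."""

    event_id: str
    branch_species: Tuple[str, ...]
    age_ks: float
    retention_prob: float
    surviving_pairs: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)

    def all_pairs(self) -> List[Tuple[str, str]]:
        out = []
        for sp in sorted(self.surviving_pairs):
            out.extend(self.surviving_pairs[sp])
        return out


class GroundTruth:
    """Known answers of one simulated dataset.

    Holds family membership per gene, the gene genealogy (lineage nodes with
    parent, creation height and creating event), per-event surviving
    duplicate pairs, and exposes the true divergence Ks of any gene pair
    (twice the per-lineage height of their genealogical split).
    """

    def __init__(self):
        self.family_of: Dict[str, int] = {}
        self.species_of: Dict[str, str] = {}
        self.lineage_of: Dict[str, int] = {}
        # lineage id -> (parent lineage id | None, creation height, event tag)
        self.registry: Dict[int, Tuple[Optional[int], float, str]] = {}
        self.events: List[TrueEvent] = []
        self.capped_genes: List[str] = []

    def _path(self, lineage: int) -> List[int]:
        path = []
        node: Optional[int] = lineage
        while node is not None:
            path.append(node)
            node = self.registry[node][0]
        return path

    def divergence_height(self, gene_a: str, gene_b: str) -> float:
        """Per-lineage height at which the two genes' lineages split."""
        pa = self._path(self.lineage_of[gene_a])
        pb = self._path(self.lineage_of[gene_b])
        aset = set(pa)
        prev = None
        for node in pb:
            if node in aset:
                if prev is None:
                    raise ValueError("one gene is ancestral to the other")
                return self.registry[prev][1]
            prev = node
        raise ValueError(f"{gene_a} and {gene_b} share no ancestor (different families)")

    def true_ks(self, gene_a: str, gene_b: str) -> float:
        """Expected pairwise Ks of the pair: twice the split height."""
        return 2.0 * self.divergence_height(gene_a, gene_b)

    def divergence_event(self, gene_a: str, gene_b: str) -> str:
        """Event tag ('wgd0', 'sp<node>', 'ssd', 'root') of the pair's split."""
        pa = self._path(self.lineage_of[gene_a])
        pb = self._path(self.lineage_of[gene_b])
        aset = set(pa)
        prev = None
        for node in pb:
            if node in aset:
                return self.registry[prev][2]
            prev = node
        raise ValueError("no shared ancestor")

    def to_json(self, path) -> None:
        payload = {
            "family_of": self.family_of,
            "species_of": self.species_of,
            "capped_genes": self.capped_genes,
            "events": [
                {
                    "event_id": e.event_id,
                    "branch_species": list(e.branch_species),
                    "age_ks": e.age_ks,
                    "retention_prob": e.retention_prob,
                    "surviving_pairs": {
                        sp: [list(p) for p in pairs]
                        for sp, pairs in sorted(e.surviving_pairs.items())
                    },
                }
                for e in self.events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimResult:
    genomes: Dict[str, SpeciesGenome]
    cds: CodingSequenceSet
    homology: List[HomologyEdge]
    truth: GroundTruth
    species_tree: SpeciesTree


# ---------------------------------------------------------------------------
# The simulator


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = SpeciesTree.from_newick(config.species_newick)
        self.height = self._heights()
        self.truth = GroundTruth()
        self._next_lineage = 0
        self._events_by_branch: Dict[int, List[Tuple[float, int]]] = {}
        self._validate_events()

    # -- tree geometry -----------------------------------------------------

    def _heights(self) -> List[float]:
        h = [0.0] * self.tree.n_nodes
        for i in range(self.tree.n_nodes):  # post-order ids: children first
            if self.tree.children[i]:
                hs = [
                    h[c] + (self.tree.branch_length[c] or 0.0)
                    for c in self.tree.children[i]
                ]
                if max(hs) - min(hs) > 1e-6:
                    raise ValueError("species tree must be ultrametric in Ks units")
                h[i] = hs[0]
        return h

    def _validate_events(self):
        for k, ev in enumerate(self.cfg.wgd_events):
            child = self.tree.mrca(ev.species())
            if self.tree.node_species(child) != frozenset(ev.species()):
                raise ValueError(
                    f"WGD branch {ev.species()} is not a clade of the species tree"
                )
            parent = self.tree.parent[child]
            he = ev.age_ks / 2.0
            lo = self.height[child]
            hi = self.height[parent] if parent is not None else None
            if hi is None or he > hi + 1e-9:
                raise ValueError(
                    f"WGD at age_ks={ev.age_ks} is older than the top of its branch"
                )
            if he < lo - 1e-9:
                raise ValueError(
                    f"WGD at age_ks={ev.age_ks} is younger than the bottom of its branch"
                )
            self._events_by_branch.setdefault(child, []).append((he, k))
        for evs in self._events_by_branch.values():
            evs.sort(key=lambda t: -t[0])  # oldest first going down the branch

    # -- genealogy ---------------------------------------------------------

    def _new_lineage(self, parent: Optional[int], height: float, event: str) -> int:
        lid = self._next_lineage
        self._next_lineage += 1
        self.truth.registry[lid] = (parent, height, event)
        return lid

    # -- genome construction ----------------------------------------------

    def _root_genome(self) -> GenomeState:
        cfg = self.cfg
        codon_idx = self.rng.integers(0, len(SENSE_CODONS), (cfg.n_families, cfg.cds_codons))
        state: GenomeState = []
        fam = 0
        h_root = self.height[self.tree.root_id]
        for _ in range(cfg.n_scaffolds):
            scaf: List[SimGene] = []
            for _ in range(cfg.genes_per_scaffold):
                if fam >= cfg.n_families:
                    break
                seq = "".join(SENSE_CODONS[i] for i in codon_idx[fam])
                lid = self._new_lineage(None, h_root, "root")
                scaf.append(SimGene(lineage=lid, family=fam, seq=seq))
                fam += 1
            if scaf:
                state.append(scaf)
        return state

    def _evolve_segment(self, state: GenomeState, h_from: float, h_to: float) -> GenomeState:
        """Evolve every gene down a branch segment of per-lineage length
        h_from - h_to, with fractionation of redundant copies and tandem
        duplications."""
        cfg = self.cfg
        dh = h_from - h_to
        if dh <= 1e-12:
            return state
        copies: Dict[int, int] = {}
        for scaf in state:
            for g in scaf:
                copies[g.family] = copies.get(g.family, 0) + 1
        p_loss = 1.0 - math.exp(-cfg.fractionation_prob * dh)
        p_dup = 1.0 - math.exp(-cfg.small_scale_dup_rate * dh)
        new_state: GenomeState = []
        for scaf in state:
            new_scaf: List[SimGene] = []
            for g in scaf:
                if copies[g.family] >= 2 and self.rng.random() < p_loss:
                    copies[g.family] -= 1
                    continue
                if p_dup > 0 and self.rng.random() < p_dup:
                    h_dup = h_to + self.rng.uniform(0.0, dh)
                    seq_at_dup, cap0 = _evolve(g.seq, h_from - h_dup, cfg.omega, self.rng)
                    for _ in range(2):
                        lid = self._new_lineage(g.lineage, h_dup, "ssd")
                        seq, cap = _evolve(seq_at_dup, h_dup - h_to, cfg.omega, self.rng)
                        new_scaf.append(
                            SimGene(
                                lineage=lid, family=g.family, seq=seq,
                                strand=g.strand, capped=g.capped or cap0 or cap,
                            )
                        )
                    copies[g.family] += 1
                else:
                    seq, cap = _evolve(g.seq, dh, cfg.omega, self.rng)
                    new_scaf.append(
                        SimGene(
                            lineage=g.lineage, family=g.family, seq=seq,
                            strand=g.strand, capped=g.capped or cap,
                        )
                    )
            new_state.append(new_scaf)
        return new_state

    def _apply_wgd(self, state: GenomeState, he: float, ev_idx: int) -> GenomeState:
        ev = self.cfg.wgd_events[ev_idx]
        tag = f"wgd{ev_idx}"

        def duplicate(g: SimGene) -> Tuple[SimGene, SimGene]:
            l1 = self._new_lineage(g.lineage, he, tag)
            l2 = self._new_lineage(g.lineage, he, tag)
            c1 = SimGene(lineage=l1, family=g.family, seq=g.seq, strand=g.strand, capped=g.capped)
            c2 = SimGene(lineage=l2, family=g.family, seq=g.seq, strand=g.strand, capped=g.capped)
            return c1, c2

        return apply_wgd(state, ev.retention_prob, self.rng, duplicate_fn=duplicate)

    def _speciate(self, state: GenomeState, h: float, node: int) -> GenomeState:
        tag = f"sp{node}"
        return [
            [
                SimGene(
                    lineage=self._new_lineage(g.lineage, h, tag),
                    family=g.family, seq=g.seq, strand=g.strand, capped=g.capped,
                )
                for g in scaf
            ]
            for scaf in state
        ]

    # -- main recursion ----------------------------------------------------

    def run(self) -> SimResult:
        tips: Dict[str, GenomeState] = {}
        root = self.tree.root_id
        self._descend(self._root_genome(), root, tips, entering=True)
        return self._emit(tips)

    def _descend(self, state: GenomeState, node: int, tips: Dict[str, GenomeState], entering: bool):
        children = self.tree.children[node]
        if not children:
            tips[self.tree.label[node]] = apply_inversions(
                state, self.cfg.n_inversions, self.rng
            )
            return
        h = self.height[node]
        speciation = len(children) >= 2
        for child in children:
            sub = self._speciate(state, h, node) if speciation else state
            sub = self._branch(sub, child)
            self._descend(sub, child, tips, entering=False)

    def _branch(self, state: GenomeState, child: int) -> GenomeState:
        h_top = self.height[self.tree.parent[child]]
        h_bot = self.height[child]
        cur = h_top
        for he, ev_idx in self._events_by_branch.get(child, []):
            state = self._evolve_segment(state, cur, he)
            state = self._apply_wgd(state, he, ev_idx)
            cur = he
        return self._evolve_segment(state, cur, h_bot)

    # -- emission ----------------------------------------------------------

    def _emit(self, tips: Dict[str, GenomeState]) -> SimResult:
        truth = self.truth
        cds = CodingSequenceSet()
        genomes: Dict[str, SpeciesGenome] = {}
        gene_of_lineage: Dict[int, str] = {}
        by_family: Dict[int, List[str]] = {}
        for sp in sorted(tips):
            state = tips[sp]
            counter = 0
            scaffolds: Dict[str, List[GeneRecord]] = {}
            for si, scaf in enumerate(state):
                recs = []
                for rank, g in enumerate(scaf):
                    gid = f"{sp}_g{counter:05d}"
                    counter += 1
                    recs.append(GeneRecord(gene_id=gid, rank=rank, strand=g.strand))
                    cds.add(gid, g.seq, validate=False)
                    truth.family_of[gid] = g.family
                    truth.species_of[gid] = sp
                    truth.lineage_of[gid] = g.lineage
                    if g.capped:
                        truth.capped_genes.append(gid)
                    gene_of_lineage[g.lineage] = gid
                    by_family.setdefault(g.family, []).append(gid)
                if recs:
                    scaffolds[f"{sp}_s{si}"] = recs
            genomes[sp] = SpeciesGenome(sp, scaffolds)

        homology = self._homology(by_family, cds)
        self._surviving_pairs(by_family)
        return SimResult(
            genomes=genomes, cds=cds, homology=homology,
            truth=truth, species_tree=self.tree,
        )

    def _homology(self, by_family: Dict[int, List[str]], cds: CodingSequenceSet) -> List[HomologyEdge]:
        edges: List[HomologyEdge] = []
        for fam in sorted(by_family):
            members = by_family[fam]
            prots = {m: _translate(cds[m]) for m in members}
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pa, pb = prots[a], prots[b]
                    diff = sum(1 for x, y in zip(pa, pb) if x != y)
                    p_dist = diff / len(pa)
                    bitscore = (1.0 - p_dist) * len(pa)
                    evalue = max(10.0 ** (-bitscore / 10.0), _EVALUE_FLOOR)
                    edges.append(HomologyEdge(a, b, bitscore=bitscore, evalue=evalue))
                    edges.append(HomologyEdge(b, a, bitscore=bitscore, evalue=evalue))
        return edges

    def _surviving_pairs(self, by_family: Dict[int, List[str]]):
        truth = self.truth
        events = [
            TrueEvent(
                event_id=f"wgd{k}",
                branch_species=ev.species(),
                age_ks=ev.age_ks,
                retention_prob=ev.retention_prob,
            )
            for k, ev in enumerate(self.cfg.wgd_events)
        ]
        by_id = {e.event_id: e for e in events}
        for fam in sorted(by_family):
            members = by_family[fam]
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if truth.species_of[a] != truth.species_of[b]:
                        continue
                    tag = truth.divergence_event(a, b)
                    if tag in by_id:
                        sp = truth.species_of[a]
                        by_id[tag].surviving_pairs.setdefault(sp, []).append((a, b))
        truth.events = events


def _translate(cds: str) -> str:
    return "".join(CODON_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate one multi-species dataset with full ground truth.

    Identical seeds give identical datasets.  Raises on infeasible configs
    (a WGD older than the top of its branch, non-ultrametric tree).
    """
    return _Simulator(config).run()


def write_dataset(result: SimResult, out_dir) -> None:
    """Emit gene_map.tsv, cds.fasta, homology.tsv, species_tree.nwk, truth.json."""
    import os

    from .io import write_cds_fasta

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "gene_map.tsv"), "w") as fh:
        fh.write("# coordinates: rank*1000 (1-based), ordering keys only\n")
        for sp in sorted(result.genomes):
            genome = result.genomes[sp]
            for scaf in sorted(genome.scaffolds):
                for g in genome.scaffolds[scaf]:
                    start = g.rank * 1000 + 1
                    fh.write(
                        f"{sp}\t{g.gene_id}\t{scaf}\t{start}\t{start + 900}\t{g.strand}\n"
                    )
    write_cds_fasta(result.cds, os.path.join(out_dir, "cds.fasta"))
    with open(os.path.join(out_dir, "homology.tsv"), "w") as fh:
        for e in result.homology:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.bitscore:.4f}\t{e.evalue:.6g}\n")
    with open(os.path.join(out_dir, "species_tree.nwk"), "w") as fh:
        fh.write(result.species_tree.to_newick() + "\n")
    result.truth.to_json(os.path.join(out_dir, "truth.json"))
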