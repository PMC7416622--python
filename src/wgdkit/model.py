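"""Shared domain types for the WGD-inference pipeline.

The internal genome model is rank-based: base-pair coordinates are used only
to order genes along a scaffold, after which each gene is identified by its
0-based rank.  Collinearity, duplication depth and anchor detection all
operate on gene order, which is what survives assembly fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "GeneRecord",
    "SpeciesGenome",
    "HomologyEdge",
    "CodingSequenceSet",
    "PipelineConfig",
    "GeneFamily",
    "WeightedKsEntry",
    "KsDistribution",
    "OrthologPair",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    rank: int
    strand: str  # "+" or "-"


class SpeciesGenome:
    """Ordered gene ranks per scaffold for one species.

    Ranks within each scaffold are 0..k-1 with no gaps; gene ids are unique
    within the species.
    """

    def __init__(self, species_id: str, scaffolds: Dict[str, List[GeneRecord]]):
        self.species_id = species_id
        self.scaffolds: Dict[str, List[GeneRecord]] = {}
        seen: set[str] = set()
        for scaf, genes in scaffolds.items():
            ordered = sorted(genes, key=lambda g: g.rank)
            ranks = [g.rank for g in ordered]
            if ranks != list(range(len(ordered))):
                raise ValueError(
                    f"scaffold {scaf!r}: ranks must be 0..k-1 without gaps"
                )
            for g in ordered:
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r} in {species_id!r}")
                seen.add(g.gene_id)
            self.scaffolds[scaf] = ordered
        self._locate = {
            g.gene_id: (scaf, g.rank)
            for scaf, genes in self.scaffolds.items()
            for g in genes
        }

    @property
    def gene_ids(self) -> List[str]:
        return list(self._locate)

    @property
    def n_genes(self) -> int:
        return len(self._locate)

    def locate(self, gene_id: str) -> Tuple[str, int]:
        """(scaffold, rank) of a gene."""
        return self._locate[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._locate

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpeciesGenome({self.species_id!r}, {len(self.scaffolds)} scaffolds, "
            f"{self.n_genes} genes)"
        )


@dataclass
class HomologyEdge:
    """A similarity hit between two genes (directed: query -> subject)."""

    gene_a: str
    gene_b: str
    bitscore: float
    evalue: float
    cscore: Optional[float] = None  # filled by collinearity.cscore_filter

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


class CodingSequenceSet:
    """gene_id -> codon sequence (length divisible by 3, no internal stops)."""

    def __init__(self, sequences: Optional[Dict[str, str]] = None, validate: bool = True):
        self._seqs: Dict[str, str] = {}
        if sequences:
            for gid, seq in sequences.items():
                self.add(gid, seq, validate=validate)

    def add(self, gene_id: str, seq: str, validate: bool = True) -> None:
        seq = seq.upper()
        if validate:
            if len(seq) % 3 != 0:
                raise ValueError(f"{gene_id}: CDS length not divisible by 3")
            if len(seq) < 9:
                raise ValueError(f"{gene_id}: CDS shorter than 3 codons")
            # trailing stop codon is tolerated and trimmed
            if seq[-3:] in _STOPS:
                seq = seq[:-3]
            for i in range(0, len(seq) - 3 + 1, 3):
                if seq[i : i + 3] in _STOPS:
                    raise ValueError(f"{gene_id}: internal stop codon at codon {i // 3}")
        self._seqs[gene_id] = seq

    def __getitem__(self, gene_id: str) -> str:
        return self._seqs[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self):
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()


@dataclass
class PipelineConfig:
    """Printed constants of the analysis, with their published defaults.

    E-value cutoffs: 1e-10 for the within-species paranome search, 1e-5 for
    cross-species searches.  Subfamilies are cut so that pairwise Ks does not
    exceed ``subfamily_max_ks``; weak collinearity matches are dropped below
    ``cscore_min``; segments need at least ``min_anchor_pairs`` anchors
    (presets 5 / 10 / 15 depending on assembly contiguity); the WGD peak
    window for dating is ``peak_window``; gene families used for placement
    have at most ``placement_max_family_size`` genes; placements are counted
    at each bootstrap ``support_thresholds``; peak confidence intervals use
    ``bootstrap_reps`` weighted resamples at ``ci_coverage``.
    """

    paranome_evalue_cutoff: float = 1e-10
    cross_species_evalue_cutoff: float = 1e-5
    subfamily_max_ks: float = 5.0
    cscore_min: float = 0.5
    min_anchor_pairs: int = 5
    peak_window: Tuple[float, float] = (0.6, 1.4)
    placement_max_family_size: int = 300
    support_thresholds: Tuple[int, ...] = (50, 80)
    kde_bandwidth: str = "silverman"
    bootstrap_reps: int = 200
    ci_coverage: float = 0.90
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "paranome_evalue_cutoff",
            "cross_species_evalue_cutoff",
            "subfamily_max_ks",
            "cscore_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.peak_window
        if not lo < hi:
            raise ValueError("peak_window lo must be < hi")
        if not 0 < self.ci_coverage < 1:
            raise ValueError("ci_coverage must be in (0, 1)")


@dataclass
class GeneFamily:
    """A connected component of the thresholded similarity graph (>= 2 genes)."""

    family_id: str
    members: List[str]
    species: Dict[str, str] = field(default_factory=dict)  # gene_id -> species_id

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("family members must be unique")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class WeightedKsEntry:
    """One pairwise Ks estimate with its redundancy-correction weight.

    A duplication node with m cross-clade pairs contributes each pair with
    weight 1/m, so every retained duplication event carries total mass one.
    """

    gene_a: str
    gene_b: str
    ks: float
    weight: float
    node_id: str
    m: int


@dataclass
class KsDistribution:
    """A (possibly weighted) collection of pairwise Ks ages."""

    entries: List[WeightedKsEntry]
    source: str = "paranome"  # paranome | anchors | orthologs
    excluded_saturated: int = 0

    @property
    def values(self):
        return [e.ks for e in self.entries]

    @property
    def weights(self):
        return [e.weight for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit ortholog pair between two species."""

    gene_a: str
    gene_b: str
    bitscore: float
    evalue: float
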