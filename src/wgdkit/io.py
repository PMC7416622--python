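"""Readers and writers for the standard formats the pipeline touches.

Gene maps come in as GFF3 (gene features, 1-based inclusive coordinates) or
as a 6-column TSV (species, gene_id, scaffold, start, end, strand).  Either
way base-pair coordinates are only used to order genes; the internal model
keeps 0-based ranks.  Homology tables are BLAST outfmt-6-like (qseqid,
sseqid, bitscore, evalue).  All readers are deterministic given file bytes
and independent of input row order.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .model import CodingSequenceSet, GeneRecord, HomologyEdge, SpeciesGenome

__all__ = [
    "read_gene_map",
    "read_gene_maps",
    "read_homology_table",
    "read_cds_fasta",
    "write_cds_fasta",
    "write_tsv",
]

GENE_MAP_COLUMNS = ["species", "gene_id", "scaffold", "start", "end", "strand"]


def _rank_genomes(rows: pd.DataFrame) -> Dict[str, SpeciesGenome]:
    genomes: Dict[str, SpeciesGenome] = {}
    for species, sub in rows.groupby("species", sort=True):
        dup = sub["gene_id"][sub["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate gene_id {dup.iloc[0]!r} in gene map for species {species!r}"
            )
        scaffolds: Dict[str, List[GeneRecord]] = {}
        for scaf, genes in sub.groupby("scaffold", sort=True):
            ordered = genes.sort_values(["start", "gene_id"], kind="mergesort")
            scaffolds[str(scaf)] = [
                GeneRecord(gene_id=str(g.gene_id), rank=i, strand=str(g.strand))
                for i, g in enumerate(ordered.itertuples())
            ]
        genomes[str(species)] = SpeciesGenome(str(species), scaffolds)
    return genomes


def read_gene_maps(path, format: str = "tsv") -> Dict[str, SpeciesGenome]:
    """Read a gene map file possibly containing several species."""
    if format == "tsv":
        rows = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            names=GENE_MAP_COLUMNS,
            header=None,
            dtype={"species": str, "gene_id": str, "scaffold": str, "strand": str},
        )
        # tolerate a header row
        if len(rows) and rows.iloc[0]["gene_id"] == "gene_id":
            rows = rows.iloc[1:].reset_index(drop=True)
        rows["start"] = pd.to_numeric(rows["start"])
    elif format == "gff3":
        rows = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene map format {format!r}")
    return _rank_genomes(rows)


def read_gene_map(path, format: str = "tsv", species: Optional[str] = None) -> SpeciesGenome:
    """Read the gene map of a single species (ranks assigned by start coordinate)."""
    genomes = read_gene_maps(path, format=format)
    if species is not None:
        if species not in genomes:
            raise KeyError(f"species {species!r} not present in {path}")
        return genomes[species]
    if len(genomes) != 1:
        raise ValueError(
            f"{path} contains {len(genomes)} species; pass species= to select one"
        )
    return next(iter(genomes.values()))


def _read_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    records = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        records.append(
            {
                "species": feat.attributes.get("species", ["genome"])[0],
                "gene_id": gid,
                "scaffold": feat.seqid,
                "start": int(feat.start),  # GFF3 is 1-based inclusive
                "end": int(feat.end),
                "strand": feat.strand or "+",
            }
        )
    return pd.DataFrame.from_records(
        records, columns=GENE_MAP_COLUMNS
    )


def read_homology_table(path, evalue_cutoff: float = 1e-10) -> List[HomologyEdge]:
    """Read an outfmt-6-like table (qseqid, sseqid, bitscore, evalue).

    Hits with evalue above the cutoff and self-hits are dropped.  Reciprocal
    duplicates (a,b)/(b,a) are kept separately; reciprocal-best-hit search
    needs the directionality.
    """
    rows = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["query", "subject", "bitscore", "evalue"],
        dtype={"query": str, "subject": str},
        keep_default_na=False,
    )
    for col in ("bitscore", "evalue"):
        coerced = pd.to_numeric(rows[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric {col} {rows[col][bad.idxmax()]!r} at line {line}"
            )
        rows[col] = coerced
    edges = []
    for r in rows.itertuples():
        if r.query == r.subject:
            continue
        if r.evalue > evalue_cutoff:
            continue
        edges.append(
            HomologyEdge(gene_a=r.query, gene_b=r.subject, bitscore=float(r.bitscore), evalue=float(r.evalue))
        )
    return edges


def read_cds_fasta(path) -> CodingSequenceSet:
    """Read coding sequences (FASTA); validates frame and internal stops."""
    cds = CodingSequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        cds.add(rec.id, str(rec.seq))
    return cds


def write_cds_fasta(cds: CodingSequenceSet, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(cds):
            fh.write(f">{gid}\n{cds[gid]}\n")


def write_tsv(records: Iterable[dict], path, columns: Optional[Sequence[str]] = None) -> None:
    """Write records as a TSV with a header line."""
    df = pd.DataFrame.from_records(list(records), columns=columns)
    df.to_csv(path, sep="\t", index=False)
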