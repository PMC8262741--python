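"""Project data model: genomes, contigs, genes, and ingestion.

A genome is a set of 1..n contigs (all replicons of an organism may be
combined into one "organism genome"); a contig carries an ordered list of
protein-coding genes. All downstream computation — alignment, the chunked
hit store, reciprocal-best-hit orthology — operates on the dense integer
gene/contig/genome ids assigned here at ingestion time.

Identical paralogs (byte-identical protein sequences within one genome) are
collapsed during project setup; the surviving representative is the copy
with the lowest gene id and removed copies are retained as aliases for
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("orthopan")


@dataclass
class Gene:
    """One protein-coding gene; the unit of alignment and orthology."""

    gene_id: int
    contig_id: int
    locus_tag: str
    start: int  # 1-based inclusive nucleotide coordinate (0 sentinel for FASTA input)
    end: int
    strand: str  # '+' or '-'
    protein_seq: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class Contig:
    contig_id: int
    accession: str
    length_bp: int
    genes: list[int] = field(default_factory=list)  # gene ids ordered by start


@dataclass
class Genome:
    genome_id: int
    name: str
    contig_ids: set[int] = field(default_factory=set)


@dataclass
class Project:
    """A comparative-genomics project: genomes, their contigs and genes.

    ``paralog_aliases`` maps each removed identical-paralog gene id to its
    surviving representative; aliased genes are excluded from every active
    gene list and therefore from all counts downstream.
    """

    name: str = "project"
    genomes: list[Genome] = field(default_factory=list)
    contigs: dict[int, Contig] = field(default_factory=dict)
    genes: dict[int, Gene] = field(default_factory=dict)
    paralog_aliases: dict[int, int] = field(default_factory=dict)

    # -- id bookkeeping -------------------------------------------------
    def _next_genome_id(self) -> int:
        return len(self.genomes)

    def _next_contig_id(self) -> int:
        return max(self.contigs, default=-1) + 1

    def _next_gene_id(self) -> int:
        return max(self.genes, default=-1) + 1

    # -- lookups --------------------------------------------------------
    def genome_by_name(self, name: str) -> Genome:
        for g in self.genomes:
            if g.name == name:
                return g
        raise KeyError(f"no genome named {name!r}")

    def genome_of_contig(self, contig_id: int) -> Genome:
        for g in self.genomes:
            if contig_id in g.contig_ids:
                return g
        raise KeyError(f"contig {contig_id} belongs to no genome")

    def contig_of_gene(self, gene_id: int) -> int:
        return self.genes[gene_id].contig_id

    def active_genes(self, genome_id: int) -> list[int]:
        """Gene ids of a genome after paralog filtering, in locus order."""
        genome = self.genomes[genome_id]
        out: list[int] = []
        for cid in sorted(genome.contig_ids):
            out.extend(
                gid for gid in self.contigs[cid].genes if gid not in self.paralog_aliases
            )
        return out

    def all_active_genes(self) -> list[int]:
        out: list[int] = []
        for g in self.genomes:
            out.extend(self.active_genes(g.genome_id))
        return sorted(out)

    def validate(self) -> None:
        """Check the structural invariants (partition of genes and contigs)."""
        seen_contigs: set[int] = set()
        for g in self.genomes:
            if not g.contig_ids:
                raise ValueError(f"genome {g.name}: a genome is a set of at least one contig")
            overlap = seen_contigs & g.contig_ids
            if overlap:
                raise ValueError(f"contigs {sorted(overlap)} shared between genomes")
            seen_contigs |= g.contig_ids
        for gid, gene in self.genes.items():
            if gene.contig_id not in self.contigs:
                raise ValueError(f"gene {gid} on unknown contig {gene.contig_id}")
        for alias in self.paralog_aliases:
            for g in self.genomes:
                if alias in self.active_genes(g.genome_id):  # pragma: no cover
                    raise ValueError(f"aliased gene {alias} still active")


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def _protein_from_cds(feature, record) -> str | None:
    """Protein sequence of a CDS: /translation verbatim, else translate the span.

    Compound (join) locations without a /translation qualifier are skipped —
    bespoke splicing is irrelevant here and a missing translation on a
    joined CDS usually signals a pseudogene.
    """
    quals = feature.qualifiers
    if "translation" in quals:
        return quals["translation"][0].strip("*")
    if len(feature.location.parts) > 1:
        return None
    try:
        nt = feature.extract(record.seq)
        prot = str(Seq(nt).translate(table=1))
    except Exception:
        return None
    prot = prot.rstrip("*")
    if not prot or "*" in prot:
        return None
    return prot


def ingest_genbank(path: str | Path, genome_name: str, project: Project) -> Project:
    """Add one genome from a GenBank flat file.

    One contig per LOCUS record, one gene per CDS feature. CDS features
    without a usable protein sequence are skipped with a warning; a file
    with no CDS at all is an error.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no coding sequences (empty or not GenBank)")
    genome = Genome(project._next_genome_id(), genome_name)
    n_genes = 0
    for record in records:
        cid = project._next_contig_id()
        contig = Contig(cid, record.id or record.name, len(record.seq))
        project.contigs[cid] = contig
        genome.contig_ids.add(cid)
        cds = [f for f in record.features if f.type == "CDS"]
        cds.sort(key=lambda f: int(f.location.start))
        for feature in cds:
            prot = _protein_from_cds(feature, record)
            locus = feature.qualifiers.get("locus_tag", [f"{record.id}_{n_genes}"])[0]
            if not prot:
                logger.warning("skipping CDS %s: no translation and no usable span", locus)
                continue
            gid = project._next_gene_id()
            gene = Gene(
                gene_id=gid,
                contig_id=cid,
                locus_tag=locus,
                start=int(feature.location.start) + 1,
                end=int(feature.location.end),
                strand="-" if feature.location.strand == -1 else "+",
                protein_seq=prot,
                product=feature.qualifiers.get("product", [""])[0],
            )
            project.genes[gid] = gene
            contig.genes.append(gid)
            n_genes += 1
    if n_genes == 0:
        raise ValueError(f"{path}: no coding sequences")
    project.genomes.append(genome)
    return project


def ingest_fasta_pair(
    protein_fasta: str | Path,
    contig_map: pd.DataFrame | str | Path,
    genome_name: str,
    project: Project,
) -> Project:
    """Add one genome from a protein FASTA plus a sequence→contig map.

    ``contig_map`` is a table (or TSV path) with columns ``seq_id``,
    ``contig_accession``, ``genome_name``. Nucleotide coordinates are
    unknown for FASTA input and set to the documented 0/0 sentinel,
    strand '+'.
    """
    if not isinstance(contig_map, pd.DataFrame):
        contig_map = pd.read_csv(contig_map, sep="\t", dtype=str)
    cmap = contig_map[contig_map["genome_name"] == genome_name]
    seq_to_acc: dict[str, str] = dict(zip(cmap["seq_id"], cmap["contig_accession"]))

    records = list(SeqIO.parse(str(protein_fasta), "fasta"))
    seen: set[str] = set()
    genome = Genome(project._next_genome_id(), genome_name)
    contigs_by_acc: dict[str, Contig] = {}
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in seq_to_acc:
            raise ValueError(f"sequence {rec.id!r} not present in contig map")
        acc = seq_to_acc[rec.id]
        if acc not in contigs_by_acc:
            cid = project._next_contig_id()
            contig = Contig(cid, acc, 0)
            project.contigs[cid] = contig
            contigs_by_acc[acc] = contig
            genome.contig_ids.add(cid)
        contig = contigs_by_acc[acc]
        gid = project._next_gene_id()
        gene = Gene(gid, contig.contig_id, rec.id, 0, 0, "+",
                    str(rec.seq).rstrip("*"), rec.description.partition(" ")[2])
        project.genes[gid] = gene
        contig.genes.append(gid)
    if not records:
        raise ValueError(f"{protein_fasta}: no sequences")
    project.genomes.append(genome)
    return project


def filter_identical_paralogs(project: Project, genome_id: int) -> Project:
    """Collapse byte-identical protein sequences within one genome.

    Genome-wide (across all contigs of the genome); the representative is
    the copy with the lowest gene id, i.e. first in locus order. Idempotent.
    """
    genome = project.genomes[genome_id]
    by_seq: dict[str, int] = {}
    gene_ids = sorted(
        gid
        for cid in genome.contig_ids
        for gid in project.contigs[cid].genes
        if gid not in project.paralog_aliases
    )
    for gid in gene_ids:
        seq = project.genes[gid].protein_seq
        if seq in by_seq:
            project.paralog_aliases[gid] = by_seq[seq]
        else:
            by_seq[seq] = gid
    return project


# ---------------------------------------------------------------------------
# Manifest round-trip (TSV trio + paralog aliases + protein FASTA)
# ---------------------------------------------------------------------------

def write_manifests(project: Project, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(g.genome_id, g.name, ",".join(map(str, sorted(g.contig_ids))))
         for g in project.genomes],
        columns=["genome_id", "name", "contig_ids"],
    ).to_csv(outdir / "genomes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.contig_id, c.accession, c.length_bp) for c in project.contigs.values()],
        columns=["contig_id", "accession", "length_bp"],
    ).to_csv(outdir / "contigs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g.gene_id, g.contig_id, g.locus_tag, g.start, g.end, g.strand, g.product)
         for g in project.genes.values()],
        columns=["gene_id", "contig_id", "locus_tag", "start", "end", "strand", "product"],
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(project.paralog_aliases.items()),
        columns=["removed_gene_id", "representative_gene_id"],
    ).to_csv(outdir / "paralog_aliases.tsv", sep="\t", index=False)
    with open(outdir / "proteins.faa", "w") as fh:
        for gid in sorted(project.genes):
            fh.write(f">{gid}\n{project.genes[gid].protein_seq}\n")
    with open(outdir / "project.txt", "w") as fh:
        fh.write(project.name + "\n")


def read_manifests(indir: str | Path) -> Project:
    indir = Path(indir)
    project = Project(name=(indir / "project.txt").read_text().strip())
    contigs = pd.read_csv(indir / "contigs.tsv", sep="\t")
    for row in contigs.itertuples():
        project.contigs[int(row.contig_id)] = Contig(int(row.contig_id), str(row.accession), int(row.length_bp))
    seqs = {int(r.id): str(r.seq) for r in SeqIO.parse(str(indir / "proteins.faa"), "fasta")}
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", keep_default_na=False)
    for row in genes.itertuples():
        gid = int(row.gene_id)
        project.genes[gid] = Gene(gid, int(row.contig_id), str(row.locus_tag),
                                  int(row.start), int(row.end), str(row.strand),
                                  seqs[gid], str(row.product))
        project.contigs[int(row.contig_id)].genes.append(gid)
    for c in project.contigs.values():
        c.genes.sort(key=lambda gid: (project.genes[gid].start, gid))
    genomes = pd.read_csv(indir / "genomes.tsv", sep="\t")
    for row in genomes.itertuples():
        cids = set(int(x) for x in str(row.contig_ids).split(",") if x != "")
        project.genomes.append(Genome(int(row.genome_id), str(row.name), cids))
    project.genomes.sort(key=lambda g: g.genome_id)
    aliases = pd.read_csv(indir / "paralog_aliases.tsv", sep="\t")
    for row in aliases.itertuples():
        project.paralog_aliases[int(row.removed_gene_id)] = int(row.representative_gene_id)
    return project
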