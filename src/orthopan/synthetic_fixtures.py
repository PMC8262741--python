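"""Desk-scale synthetic projects with planted ground truth.

The generator emulates the inputs of a comparative-genomics project —
multiple genomes of 1..n contigs, protein-coding genes, and a consistent
all-vs-all hit table — with a fully known truth: planted ortholog clusters
(core, accessory, per-genome singletons), identical paralog copies, and
controllable score noise.

Planted structure of the hit table:

* every active gene has a self-hit at 100% identity, full length, with the
  maximal bit score for its length (2 bits per residue);
* cluster mates in different genomes hit each other near ``identity_base``
  percent identity, with bit score proportional to identity × length plus
  Gaussian noise of sd ``score_noise_sd``;
* each within-cluster hit is accompanied by one *decoy* hit to a different
  cluster's member at identity_base − 5 identity, so that score noise can
  overturn best-hit selection — at zero noise the true hit always wins;
* background spurious hits are planted with score ratio below 0.2, safely
  under the default 0.3 cutoff.

With ``score_noise_sd = 0`` the full pipeline must recover the planted
clusters exactly; with growing noise the planted-pair recall degrades.
Sequences are random amino-acid strings with cluster mates derived by
seeded point substitutions at the target identity, so a real aligner run
on the emitted FASTA/GenBank files yields qualitatively consistent hits;
the primary test path consumes the emitted hit table directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (Contig, Gene, Genome, Project,
                           filter_identical_paralogs)
from .hitstore import HitRecord, hits_to_table

_AA = "ACDEFGHIKLMNPQRSTVWY"
#: one arbitrary codon per amino acid, for back-translating emitted GenBank
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

SELF_BITS_PER_RESIDUE = 2.0  # self-hit bit score = 2 bits per residue
DECOY_IDENTITY_OFFSET = 5.0  # decoy hits sit this far below identity_base
SPURIOUS_SRV_MAX = 0.2       # background hits stay below this score ratio


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic project; seed-determined throughout."""

    n_genomes: int = 4
    contigs_per_genome: tuple[int, int] = (1, 3)  # inclusive range
    n_core: int = 30
    n_accessory: int = 10
    accessory_presence_prob: float = 0.5
    singletons_per_genome: int = 4
    identical_paralog_rate: float = 0.0
    score_noise_sd: float = 0.0
    identity_base: float = 80.0
    protein_len_range: tuple[int, int] = (100, 240)
    spurious_per_gene: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if min(self.n_core, self.n_accessory, self.singletons_per_genome) < 0:
            raise ValueError("cluster counts must be non-negative")
        if self.n_core + self.n_accessory + self.singletons_per_genome == 0:
            raise ValueError("infeasible spec: zero genes per genome")
        if not 0 <= self.accessory_presence_prob <= 1:
            raise ValueError("accessory_presence_prob must be in [0,1]")
        if not 0 <= self.identical_paralog_rate <= 1:
            raise ValueError("identical_paralog_rate must be in [0,1]")
        if self.n_accessory > 0 and self.n_genomes < 3:
            raise ValueError("accessory clusters need at least 3 genomes")


@dataclass
class GroundTruth:
    """Planted structure, expressed in final project gene ids."""

    clusters: list[dict[int, int]]  # genome_id -> active gene_id
    paralog_aliases: dict[int, int]
    ortholog_pairs: set[tuple[int, int]] = field(default_factory=set)

    def expected_counts(self, genome_ids: Sequence[int]) -> dict:
        """Expected pan/core/singleton sizes for any genome subset."""
        sel = set(genome_ids)
        pan = core = 0
        singles = {g: 0 for g in sel}
        for members in self.clusters:
            present = sel & members.keys()
            if not present:
                continue
            pan += 1
            if present == sel:
                core += 1
            if len(present) == 1:
                singles[next(iter(present))] += 1
        return {"pan": pan, "core": core, "singletons": singles}

    def pairs_for(self, genome_a: int, genome_b: int) -> set[tuple[int, int]]:
        return {
            (m[genome_a], m[genome_b])
            for m in self.clusters
            if genome_a in m and genome_b in m
        }


@dataclass
class Fixture:
    spec: FixtureSpec
    project: Project
    hits: list[HitRecord]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), length))


def _mutate(rng: np.random.Generator, seq: str, identity_pct: float) -> str:
    n_mut = int(round(len(seq) * (1.0 - identity_pct / 100.0)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = _AA.replace(out[pos], "")
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _plant_memberships(spec: FixtureSpec, rng: np.random.Generator) -> list[list[int]]:
    """Genome index sets per cluster: core, accessory (2..n-1 genomes), singletons."""
    memberships: list[list[int]] = []
    all_genomes = list(range(spec.n_genomes))
    for _ in range(spec.n_core):
        memberships.append(all_genomes.copy())
    for _ in range(spec.n_accessory):
        while True:
            sel = [g for g in all_genomes
                   if rng.random() < spec.accessory_presence_prob]
            if 2 <= len(sel) <= spec.n_genomes - 1:
                memberships.append(sel)
                break
    for g in all_genomes:
        for _ in range(spec.singletons_per_genome):
            memberships.append([g])
    return memberships


def generate(spec: FixtureSpec, out_dir: str | Path | None = None) -> Fixture:
    """Build a planted project, its hit table and ground truth.

    Identical-paralog copies are planted as extra loci and then collapsed
    with the project-setup filter, so the returned project's active genes
    are exactly the planted representatives. The same seed always yields
    byte-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    memberships = _plant_memberships(spec, rng)

    # logical genes: (cluster_idx, genome_idx) -> sequence; one shared length per cluster
    lo, hi = spec.protein_len_range
    seqs: dict[tuple[int, int], str] = {}
    for ci, genomes in enumerate(memberships):
        length = int(rng.integers(lo, hi + 1))
        base = _random_protein(rng, length)
        for g in genomes:
            seqs[(ci, g)] = _mutate(rng, base, spec.identity_base) if len(genomes) > 1 else base

    # physical gene layout per genome (logical genes + identical duplicates)
    project = Project(name=f"fixture-seed{spec.seed}")
    logical_rep: dict[tuple[int, int], int] = {}  # logical gene -> representative gene_id
    truth_aliases: dict[int, int] = {}
    clo, chi = spec.contigs_per_genome
    for g in range(spec.n_genomes):
        logicals = [key for key in seqs if key[1] == g]
        physical: list[tuple[tuple[int, int], bool]] = [(key, False) for key in logicals]
        for key in logicals:
            if rng.random() < spec.identical_paralog_rate:
                physical.append((key, True))  # identical duplicate locus
        order = rng.permutation(len(physical))
        physical = [physical[i] for i in order]
        n_contigs = int(rng.integers(clo, chi + 1))
        contig_of = rng.integers(0, n_contigs, len(physical))

        genome = Genome(len(project.genomes), f"G{g}")
        contig_ids = []
        for c in range(n_contigs):
            cid = project._next_contig_id()
            project.contigs[cid] = Contig(cid, f"G{g}_c{c}", 0)
            genome.contig_ids.add(cid)
            contig_ids.append(cid)
        project.genomes.append(genome)

        for c, cid in enumerate(contig_ids):
            pos = 0
            contig = project.contigs[cid]
            for idx in np.flatnonzero(contig_of == c):
                key, is_dup = physical[idx]
                seq = seqs[key]
                gid = project._next_gene_id()
                start = pos + 1
                end = pos + 3 * len(seq) + 3  # CDS incl. stop codon
                pos = end + 50
                strand = "+" if rng.random() < 0.8 else "-"
                gene = Gene(gid, cid, f"G{g}_{gid:05d}", start, end, strand, seq,
                            product=f"cluster {key[0]} protein" if len(memberships[key[0]]) > 1
                            else "hypothetical protein")
                project.genes[gid] = gene
                contig.genes.append(gid)
                if key in logical_rep:
                    # collapse order: lowest gene id is the representative
                    rep = min(logical_rep[key], gid)
                    other = max(logical_rep[key], gid)
                    logical_rep[key] = rep
                    truth_aliases[other] = rep
                else:
                    logical_rep[key] = gid
            contig.length_bp = pos + 100
        filter_identical_paralogs(project, genome.genome_id)

    # planted truth in final gene ids
    clusters = [
        {g: logical_rep[(ci, g)] for g in genomes}
        for ci, genomes in enumerate(memberships)
    ]
    truth = GroundTruth(clusters=clusters, paralog_aliases=truth_aliases)
    for members in clusters:
        genomes = sorted(members)
        for i, a in enumerate(genomes):
            for b in genomes[i + 1:]:
                truth.ortholog_pairs.add((members[a], members[b]))

    hits = _plant_hits(spec, project, clusters, rng)
    fixture = Fixture(spec=spec, project=project, hits=hits, truth=truth)
    if out_dir is not None:
        _emit_files(fixture, Path(out_dir))
    return fixture


def _bit(identity_pct: float, length: int, sd: float, rng: np.random.Generator) -> float:
    noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
    return max(1.0, identity_pct / 100.0 * SELF_BITS_PER_RESIDUE * length + noise)


def _plant_hits(
    spec: FixtureSpec,
    project: Project,
    clusters: list[dict[int, int]],
    rng: np.random.Generator,
) -> list[HitRecord]:
    hits: list[HitRecord] = []
    active = project.all_active_genes()
    length_of = {gid: len(project.genes[gid].protein_seq) for gid in active}

    for gid in active:  # self-hits: identity 100, maximal bit score
        n = length_of[gid]
        hits.append(HitRecord(gid, gid, 100.0, n, 0.0, SELF_BITS_PER_RESIDUE * n,
                              1, n, 1, n, n, n))

    # per genome, cluster members available as decoy targets
    members_in: dict[int, list[int]] = {}
    for ci, members in enumerate(clusters):
        if len(members) < 2:
            continue
        for g, gid in members.items():
            members_in.setdefault(g, []).append(gid)

    def cross_hit(q: int, s: int, identity: float, evalue: float) -> HitRecord:
        lq, ls = length_of[q], length_of[s]
        return HitRecord(q, s, round(identity, 2), max(lq, ls), evalue,
                         round(_bit(identity, lq, spec.score_noise_sd, rng), 2),
                         1, lq, 1, ls, lq, ls)

    for ci, members in enumerate(clusters):
        if len(members) < 2:
            continue
        genomes = sorted(members)
        for qg in genomes:
            for sg in genomes:
                if qg == sg:
                    continue
                q, s = members[qg], members[sg]
                identity = spec.identity_base
                if spec.score_noise_sd > 0:
                    identity = float(np.clip(
                        rng.normal(spec.identity_base, spec.score_noise_sd), 30.001, 100.0))
                hits.append(cross_hit(q, s, identity, 1e-50))
                # decoy: a competing hit into another cluster's member of genome sg
                decoys = [d for d in members_in.get(sg, []) if d != s]
                if decoys:
                    d = decoys[int(rng.integers(0, len(decoys)))]
                    hits.append(cross_hit(q, d, spec.identity_base - DECOY_IDENTITY_OFFSET,
                                          1e-30))

    # background spurious hits, SRV < 0.2 by construction
    n_spurious = int(len(active) * spec.spurious_per_gene)
    genome_of = {gid: project.genome_of_contig(project.genes[gid].contig_id).genome_id
                 for gid in active}
    for _ in range(n_spurious):
        q, s = (active[int(i)] for i in rng.integers(0, len(active), 2))
        if genome_of[q] == genome_of[s]:
            continue
        lq, ls = length_of[q], length_of[s]
        srv = float(rng.uniform(0.05, SPURIOUS_SRV_MAX - 0.01))
        hits.append(HitRecord(q, s, round(float(rng.uniform(30, 45)), 2),
                              max(lq, ls) // 2, 1e-12,
                              round(srv * SELF_BITS_PER_RESIDUE * lq, 2),
                              1, lq // 2, 1, ls // 2, lq, ls))
    hits.sort(key=lambda h: (h.query_gene_id, h.subject_gene_id, -h.bit_score))
    return hits


def perturb(
    hits: list[HitRecord], score_noise_sd: float, seed: int
) -> list[HitRecord]:
    """Resample only the score noise of non-self hits; identities untouched."""
    rng = np.random.default_rng(seed)
    out: list[HitRecord] = []
    for h in hits:
        if h.is_self:
            out.append(h)
            continue
        base = h.percent_identity / 100.0 * SELF_BITS_PER_RESIDUE * h.query_length
        noise = float(rng.normal(0.0, score_noise_sd)) if score_noise_sd > 0 else 0.0
        out.append(HitRecord(
            h.query_gene_id, h.subject_gene_id, h.percent_identity,
            h.alignment_length, h.evalue, round(max(1.0, base + noise), 4),
            h.query_start, h.query_end, h.subject_start, h.subject_end,
            h.query_length, h.subject_length))
    return out


# ---------------------------------------------------------------------------
# File emission (GenBank + FASTA + hit table + truth manifest)
# ---------------------------------------------------------------------------

def _emit_files(fixture: Fixture, out_dir: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out_dir.mkdir(parents=True, exist_ok=True)
    project = fixture.project
    for genome in project.genomes:
        records = []
        for cid in sorted(genome.contig_ids):
            contig = project.contigs[cid]
            nt = ["A"] * contig.length_bp
            features = []
            for gid in contig.genes:
                gene = project.genes[gid]
                cds_nt = "".join(_CODON[a] for a in gene.protein_seq) + "TAA"
                if gene.strand == "-":
                    cds_nt = str(Seq(cds_nt).reverse_complement())
                nt[gene.start - 1:gene.end] = list(cds_nt)
                features.append(SeqFeature(
                    FeatureLocation(gene.start - 1, gene.end,
                                    strand=1 if gene.strand == "+" else -1),
                    type="CDS",
                    qualifiers={"locus_tag": [gene.locus_tag],
                                "product": [gene.product],
                                "translation": [gene.protein_seq]}))
            rec = SeqRecord(Seq("".join(nt)), id=contig.accession,
                            name=contig.accession[:16],
                            description=f"synthetic contig of {genome.name}",
                            features=features)
            rec.annotations["molecule_type"] = "DNA"
            records.append(rec)
        SeqIO.write(records, out_dir / f"{genome.name}.gbk", "genbank")
        with open(out_dir / f"{genome.name}.faa", "w") as fh:
            for gid in project.active_genes(genome.genome_id):
                fh.write(f">{gid}\n{project.genes[gid].protein_seq}\n")
    hits_to_table(fixture.hits).to_csv(out_dir / "hits.tsv", sep="\t",
                                       header=False, index=False)
    truth = {
        "spec": asdict(fixture.spec),
        "clusters": [{str(g): gid for g, gid in m.items()} for m in fixture.truth.clusters],
        "paralog_aliases": {str(k): v for k, v in fixture.truth.paralog_aliases.items()},
        "expected": fixture.truth.expected_counts(
            [g.genome_id for g in project.genomes]),
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
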