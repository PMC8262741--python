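import numpy as np
import pytest

import orthopan as op
from orthopan.genome_model import Contig, Gene, Genome, Project
from orthopan.hitstore import HitRecord


@pytest.fixture(scope="session")
def zero_noise_fixture():
    return op.generate(op.FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def zero_noise_store(zero_noise_fixture, tmp_path_factory):
    prefix = tmp_path_factory.mktemp("store") / "hits"
    op.write_store(zero_noise_fixture.hits, zero_noise_fixture.project, prefix)
    return op.HitStore(prefix)


def make_project(genes_per_contig: dict[int, int], genome_contigs: list[set[int]],
                 protein_len: int = 100) -> Project:
    """Tiny hand-built project: contig id -> gene count, genome -> contig ids."""
    project = Project(name="toy")
    gid = 0
    for cid in sorted(genes_per_contig):
        contig = Contig(cid, f"c{cid}", 10_000 * (genes_per_contig[cid] + 1))
        project.contigs[cid] = contig
        for i in range(genes_per_contig[cid]):
            start = 1 + i * 1000
            gene = Gene(gid, cid, f"t{gid}", start, start + 3 * protein_len - 1,
                        "+", "M" + "A" * (protein_len - 1))
            project.genes[gid] = gene
            contig.genes.append(gid)
            gid += 1
    for i, cids in enumerate(genome_contigs):
        project.genomes.append(Genome(i, f"G{i}", set(cids)))
    return project


def make_hit(q, s, bit, pident=80.0, evalue=1e-30, qlen=100, slen=100,
             qstart=1, qend=None, alnlen=None) -> HitRecord:
    qend = qlen if qend is None else qend
    return HitRecord(q, s, pident, alnlen or qlen, evalue, bit,
                     qstart, qend, 1, slen, qlen, slen)


def self_hit(g, bit=200.0, length=100) -> HitRecord:
    return HitRecord(g, g, 100.0, length, 0.0, bit, 1, length, 1, length,
                     length, length)


def random_instance(seed: int, max_genomes: int = 6, max_hits: int = 500):
    """Random small project + flat random hit table (self-hits included).

    Scores, identities and e-values are drawn freely, so best-hit selection,
    cutoff filtering and tie-breaking are all exercised; returns
    (project, hits, genome_of).
    """
    rng = np.random.default_rng(seed)
    n_genomes = int(rng.integers(2, max_genomes + 1))
    project = Project(name=f"rand{seed}")
    genome_of: dict[int, int] = {}
    gid = 0
    for g in range(n_genomes):
        genome = Genome(g, f"G{g}")
        for c in range(int(rng.integers(1, 4))):
            cid = len(project.contigs)
            contig = Contig(cid, f"G{g}c{c}", 100_000)
            project.contigs[cid] = contig
            genome.contig_ids.add(cid)
            for i in range(int(rng.integers(1, 5))):
                length = int(rng.integers(60, 200))
                start = 1 + len(contig.genes) * 2000
                project.genes[gid] = Gene(gid, cid, f"r{gid}", start,
                                          start + 3 * length - 1, "+",
                                          "M" * length)
                contig.genes.append(gid)
                genome_of[gid] = g
                gid += 1
        project.genomes.append(genome)

    genes = sorted(project.genes)
    hits = []
    for g in genes:  # every gene gets a self-hit at its maximal score
        length = len(project.genes[g].protein_seq)
        hits.append(self_hit(g, bit=2.0 * length, length=length))
    n_cross = int(rng.integers(0, max_hits - len(genes) + 1))
    for _ in range(n_cross):
        q, s = (genes[int(i)] for i in rng.integers(0, len(genes), 2))
        if genome_of[q] == genome_of[s]:
            continue
        lq = len(project.genes[q].protein_seq)
        ls = len(project.genes[s].protein_seq)
        hits.append(HitRecord(
            q, s, float(np.round(rng.uniform(20, 100), 2)),
            int(rng.integers(30, max(lq, ls) + 1)),
            float(10.0 ** rng.uniform(-60, -6)),
            float(np.round(rng.uniform(10, 2.0 * lq), 2)),
            1, int(rng.integers(lq // 2, lq + 1)), 1, ls, lq, ls))
    return project, hits, genome_of
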