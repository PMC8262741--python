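"""Pan/core/singleton partitioning and intersection analytics.

Gene clustering is reference-seeded and iterative: every active gene of
the reference genome founds a cluster, then the remaining genomes are
processed in order and each of their genes either joins the cluster whose
*founder* it is RBH-paired with, or founds a new cluster. The resulting
clusters × genomes presence/absence matrix underlies everything else:
core genome (all-true rows), singletons (weight-one rows), Venn region
counts (≤5 genomes), UpSet intersection tables, and pan/core/singleton
accumulation curves over genome-order permutations.

Joining tests RBH against the founder only — no transitive closure — which
keeps the computation pairwise and streamable and exactly reproduces the
reference-seeded iteration; on noisy data the clustering is therefore
order-dependent (documented), though cluster *counts* on clean data are
reference-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .genome_model import Project
from .hitstore import HitStore
from .orthology import OrthologSet, OrthologyCriteria, orthologs_pairwise

VENN_MAX_SETS = 5  # Venn diagrams beyond five sets are unreadable; hard limit


@dataclass
class GeneCluster:
    cluster_id: int
    founder_gene_id: int
    founder_genome_id: int
    members: dict[int, int] = field(default_factory=dict)  # genome_id -> gene_id


@dataclass
class PanMatrix:
    """Ordered clusters × genomes presence/absence structure."""

    clusters: list[GeneCluster]
    genome_order: list[int]
    presence: np.ndarray  # bool, shape (n_clusters, n_genomes)

    @property
    def pan_size(self) -> int:
        return len(self.clusters)

    @property
    def core_mask(self) -> np.ndarray:
        return self.presence.all(axis=1)

    @property
    def core_size(self) -> int:
        return int(self.core_mask.sum())

    @property
    def singleton_mask(self) -> np.ndarray:
        return self.presence.sum(axis=1) == 1

    def to_frame(self, project: Project) -> pd.DataFrame:
        names = [project.genomes[g].name for g in self.genome_order]
        df = pd.DataFrame(self.presence.astype(int), columns=names)
        df.insert(0, "cluster_id", [c.cluster_id for c in self.clusters])
        df.insert(1, "founder_gene_id", [c.founder_gene_id for c in self.clusters])
        return df

    def to_triplets(self) -> pd.DataFrame:
        rows = [
            (c.cluster_id, genome_id, gene_id)
            for c in self.clusters
            for genome_id, gene_id in sorted(c.members.items())
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "genome_id", "gene_id"])


@dataclass
class IntersectionTable:
    rows: list[tuple[frozenset[int], int]]  # (genome-id signature, cluster count)

    def to_frame(self, project: Project) -> pd.DataFrame:
        recs = [
            (";".join(project.genomes[g].name for g in sorted(sig)), len(sig), count)
            for sig, count in self.rows
        ]
        return pd.DataFrame(recs, columns=["signature", "degree", "count"])

    def to_json(self, project: Project, genome_ids: Sequence[int]) -> str:
        return json.dumps({
            "sets": [project.genomes[g].name for g in genome_ids],
            "intersections": [
                {"signature": [project.genomes[g].name for g in sorted(sig)],
                 "degree": len(sig), "count": count}
                for sig, count in self.rows
            ],
        }, indent=2)


# ---------------------------------------------------------------------------
# Iterative reference-seeded clustering
# ---------------------------------------------------------------------------

def _ordered_genomes(genome_ids: Sequence[int], reference_id: int) -> list[int]:
    if reference_id not in genome_ids:
        raise ValueError(f"reference genome {reference_id} not in genome set")
    return [reference_id] + [g for g in genome_ids if g != reference_id]

def _partner(ortho: dict, fa: int, fb: int, gene: int) -> int | None:
    """RBH partner of ``gene`` (in genome fa) within genome fb, if any."""
    if (fa, fb) in ortho:
        return ortho[(fa, fb)].partner_of(gene, direction=0)
    if (fb, fa) in ortho:
        return ortho[(fb, fa)].partner_of(gene, direction=1)
    return None


def iterative_clusters(
    project: Project,
    genome_ids: Sequence[int],
    ortho: dict[tuple[int, int], OrthologSet],
) -> Iterator[list[GeneCluster]]:
    """Yield the cluster list after each genome is folded in.

    The first genome in ``genome_ids`` is the reference/seed. Each gene of
    a later genome joins the lowest-id cluster whose founder it is
    RBH-paired with (skipping clusters that already hold a gene of that
    genome), else founds a new cluster.
    """
    ref = genome_ids[0]
    clusters = [
        GeneCluster(i, gid, ref, members={ref: gid})
        for i, gid in enumerate(project.active_genes(ref))
    ]
    yield clusters
    for genome in genome_ids[1:]:
        # invert: for each founder genome, map partner-gene-in-G -> cluster
        claims: dict[int, GeneCluster] = {}
        for cluster in clusters:
            partner = _partner(ortho, cluster.founder_genome_id, genome,
                               cluster.founder_gene_id)
            if partner is not None and partner not in claims:
                claims[partner] = cluster
        for gid in project.active_genes(genome):
            cluster = claims.get(gid)
            if cluster is not None and genome not in cluster.members:
                cluster.members[genome] = gid
            else:
                clusters.append(GeneCluster(len(clusters), gid, genome, {genome: gid}))
        yield clusters


def _presence(clusters: list[GeneCluster], genome_order: list[int]) -> np.ndarray:
    mat = np.zeros((len(clusters), len(genome_order)), dtype=bool)
    col = {g: j for j, g in enumerate(genome_order)}
    for i, c in enumerate(clusters):
        for g in c.members:
            mat[i, col[g]] = True
    return mat


def _resolve_ortho(project, genome_ids, criteria, store, ortho, workers=1):
    if ortho is None:
        if store is None:
            raise ValueError("need either a hit store or precomputed ortholog sets")
        ortho = orthologs_pairwise(project, store, list(genome_ids), criteria, workers)
    return ortho


def pan_genome(
    project: Project,
    genome_ids: Sequence[int],
    reference_id: int,
    criteria: OrthologyCriteria = OrthologyCriteria(),
    store: HitStore | None = None,
    ortho: dict[tuple[int, int], OrthologSet] | None = None,
    workers: int = 1,
) -> PanMatrix:
    """Presence/absence matrix of all gene clusters across the genome set."""
    order = _ordered_genomes(genome_ids, reference_id)
    ortho = _resolve_ortho(project, genome_ids, criteria, store, ortho, workers)
    clusters = None
    for clusters in iterative_clusters(project, order, ortho):
        pass
    return PanMatrix(clusters=clusters, genome_order=order,
                     presence=_presence(clusters, order))


def core_genome(
    project: Project,
    genome_ids: Sequence[int],
    reference_id: int,
    criteria: OrthologyCriteria = OrthologyCriteria(),
    store: HitStore | None = None,
    ortho: dict[tuple[int, int], OrthologSet] | None = None,
) -> list[GeneCluster]:
    """Clusters present in every genome of the set."""
    pm = pan_genome(project, genome_ids, reference_id, criteria, store, ortho)
    return [c for c, ok in zip(pm.clusters, pm.core_mask) if ok]


def singletons(
    project: Project,
    genome_ids: Sequence[int],
    criteria: OrthologyCriteria = OrthologyCriteria(),
    store: HitStore | None = None,
    ortho: dict[tuple[int, int], OrthologSet] | None = None,
) -> dict[int, list[int]]:
    """Per genome, the genes found in no other genome of the set."""
    pm = pan_genome(project, genome_ids, genome_ids[0], criteria, store, ortho)
    out: dict[int, list[int]] = {g: [] for g in genome_ids}
    for c, is_single in zip(pm.clusters, pm.singleton_mask):
        if is_single:
            ((genome, gene),) = c.members.items()
            out[genome].append(gene)
    for g in out:
        out[g].sort()
    return out


# ---------------------------------------------------------------------------
# Intersections
# ---------------------------------------------------------------------------

def _signature_counts(pm: PanMatrix, genome_ids: Sequence[int]) -> dict[frozenset[int], int]:
    cols = [pm.genome_order.index(g) for g in genome_ids]
    sub = pm.presence[:, cols]
    counts: dict[frozenset[int], int] = {}
    for row in sub:
        sig = frozenset(g for g, present in zip(genome_ids, row) if present)
        if sig:
            counts[sig] = counts.get(sig, 0) + 1
    return counts


def venn_regions(pm: PanMatrix, genome_ids: Sequence[int]) -> IntersectionTable:
    """Cluster counts for every region of a ≤5-set Venn diagram.

    All 2^n − 1 regions are reported, zero counts included.
    """
    n = len(genome_ids)
    if n > VENN_MAX_SETS:
        raise ValueError("venn limited to five sets")
    if n < 2:
        raise ValueError("venn needs at least two genomes")
    counts = _signature_counts(pm, genome_ids)
    rows = []
    ids = list(genome_ids)
    for mask in range(1, 2 ** n):
        sig = frozenset(ids[i] for i in range(n) if mask >> i & 1)
        rows.append((sig, counts.get(sig, 0)))
    rows.sort(key=lambda r: (len(r[0]), sorted(r[0])))
    return IntersectionTable(rows=rows)


def upset_table(
    pm: PanMatrix,
    sort: str = "cardinality",
) -> IntersectionTable:
    """Observed intersection signatures with cluster counts.

    Sort keys: ``cardinality`` (descending count — the default ordering of
    intersection plots), ``degree`` (signature size, count-descending
    within a degree), ``deviation`` (descending observed-minus-expected
    count under independent per-genome presence frequencies).
    """
    if len(pm.genome_order) < 2:
        raise ValueError("upset needs at least two genomes")
    counts = _signature_counts(pm, pm.genome_order)
    n_clusters = pm.pan_size
    freq = {g: pm.presence[:, j].mean() for j, g in enumerate(pm.genome_order)}

    def deviation(sig: frozenset[int], count: int) -> float:
        expected = n_clusters
        for g in pm.genome_order:
            expected *= freq[g] if g in sig else (1.0 - freq[g])
        return count - expected

    items = sorted(counts.items(), key=lambda kv: sorted(kv[0]))
    if sort == "cardinality":
        items.sort(key=lambda kv: -kv[1])
    elif sort == "degree":
        items.sort(key=lambda kv: (len(kv[0]), -kv[1]))
    elif sort == "deviation":
        items.sort(key=lambda kv: -deviation(kv[0], kv[1]))
    else:
        raise ValueError(f"unknown sort key {sort!r}")
    return IntersectionTable(rows=items)


# ---------------------------------------------------------------------------
# Accumulation (development) curves
# ---------------------------------------------------------------------------

def development_curves(
    project: Project,
    genome_ids: Sequence[int],
    criteria: OrthologyCriteria = OrthologyCriteria(),
    store: HitStore | None = None,
    ortho: dict[tuple[int, int], OrthologSet] | None = None,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Pan/core/singleton sizes versus number of genomes, over orderings.

    Permutation 0 is always the input order; further orderings are drawn
    from a seeded generator. Returns, per prefix length k, the median and
    25/75% quantiles of each size over permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ortho = _resolve_ortho(project, genome_ids, criteria, store, ortho)
    rng = np.random.default_rng(seed)
    orders = [list(genome_ids)]
    for _ in range(n_permutations - 1):
        orders.append(list(rng.permutation(genome_ids)))

    sizes: dict[str, list[list[int]]] = {"pan": [], "core": [], "singleton": []}
    for order in orders:
        pan_k, core_k, single_k = [], [], []
        for clusters in iterative_clusters(project, order, ortho):
            seen = {g for c in clusters for g in c.members}
            k = len(seen)
            mat = _presence(clusters, [g for g in order if g in seen])
            pan_k.append(mat.shape[0])
            core_k.append(int(mat.all(axis=1).sum()))
            single_k.append(int((mat.sum(axis=1) == 1).sum()))
        sizes["pan"].append(pan_k)
        sizes["core"].append(core_k)
        sizes["singleton"].append(single_k)

    rows = []
    n = len(genome_ids)
    for k in range(1, n + 1):
        row: dict[str, float] = {"k": k}
        for metric, per_perm in sizes.items():
            vals = np.array([p[k - 1] for p in per_perm])
            row[f"{metric}_q25"] = float(np.percentile(vals, 25))
            row[f"{metric}_median"] = float(np.median(vals))
            row[f"{metric}_q75"] = float(np.percentile(vals, 75))
        rows.append(row)
    return pd.DataFrame(rows)


def development_sizes(
    project: Project,
    order: Sequence[int],
    ortho: dict[tuple[int, int], OrthologSet],
) -> pd.DataFrame:
    """Exact pan/core/singleton sizes along one fixed genome order."""
    rows = []
    for clusters in iterative_clusters(project, list(order), ortho):
        genomes = sorted({g for c in clusters for g in c.members})
        mat = _presence(clusters, genomes)
        rows.append({
            "k": len(genomes),
            "pan": mat.shape[0],
            "core": int(mat.all(axis=1).sum()),
            "singleton": int((mat.sum(axis=1) == 1).sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference-centric ortholog track (circular-plot data)
# ---------------------------------------------------------------------------

def reference_ortholog_table(
    pm: PanMatrix, project: Project, reference_id: int
) -> pd.DataFrame:
    """Per reference gene: coordinates, product, core flag, per-genome presence.

    This is the data behind a multi-genome circular plot: the reference's
    genes on the outer ring, core membership and each genome's ortholog
    presence on the inner rings.
    """
    if reference_id not in pm.genome_order:
        raise ValueError(f"reference genome {reference_id} not in matrix")
    cluster_of_gene = {
        c.members[reference_id]: (c, bool(ok))
        for c, ok in zip(pm.clusters, pm.core_mask)
        if reference_id in c.members
    }
    others = [g for g in pm.genome_order if g != reference_id]
    rows = []
    for gid in project.active_genes(reference_id):
        gene = project.genes[gid]
        cluster, is_core = cluster_of_gene[gid]
        row = {
            "gene_id": gid,
            "locus_tag": gene.locus_tag,
            "contig": project.contigs[gene.contig_id].accession,
            "start": gene.start, "end": gene.end, "strand": gene.strand,
            "product": gene.product,
            "core": int(is_core),
        }
        for g in others:
            row[f"in_{project.genomes[g].name}"] = int(g in cluster.members)
        rows.append(row)
    return pd.DataFrame(rows)
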