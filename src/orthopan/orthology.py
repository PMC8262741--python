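"""Reciprocal-best-hit orthology on genome hit chunks.

For an ordered genome pair (A, B) the stored contig hit chunks are merged
into the genome hit chunk of A in B and of B in A. Hits are scored with
the score ratio value (SRV) — bit score divided by the query gene's
self-hit bit score, which normalizes scores to (0, 1] — and filtered by an
e-value ceiling and an SRV cutoff. Within each direction the best hit of
every query gene is selected; best hits with reciprocal partners are
accepted as ortholog pairs.

Best-hit selection maximizes SRV first; bit score and percent identity are
secondary criteria for hits with identical score ratio, and the lowest
subject gene id breaks any remaining tie so that results are fully
deterministic and independent of scheduling.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import pandas as pd

from .genome_model import Project
from .hitstore import GenomeHitChunk, HitRecord, HitStore

logger = logging.getLogger("orthopan")


@dataclass(frozen=True)
class OrthologyCriteria:
    """Hit acceptance thresholds for RBH orthology.

    A hit survives iff evalue <= max_evalue and srv >= srv_cutoff (a hit
    exactly at the SRV cutoff is kept). The tie-break order — SRV, bit
    score, percent identity, then lowest subject gene id — is fixed.
    """

    srv_cutoff: float = 0.3
    max_evalue: float = 1e-10


@dataclass(frozen=True)
class ScoredHit:
    """A surviving hit annotated with its score ratio value."""

    hit: HitRecord
    srv: float

    @property
    def subject(self) -> int:
        return self.hit.subject_gene_id

    def sort_key(self) -> tuple:
        # maximize (srv, bit, pident); minimize subject id as final tie-break
        return (-self.srv, -self.hit.bit_score, -self.hit.percent_identity,
                self.hit.subject_gene_id)


@dataclass
class OrthologSet:
    """Accepted RBH gene pairs for one ordered genome pair."""

    genome_pair: tuple[int, int]
    pairs: set[tuple[int, int]] = field(default_factory=set)
    evidence: dict[tuple[int, int], tuple[ScoredHit, ScoredHit]] = field(default_factory=dict)

    def reversed(self) -> "OrthologSet":
        rev = OrthologSet(genome_pair=(self.genome_pair[1], self.genome_pair[0]))
        rev.pairs = {(b, a) for a, b in self.pairs}
        rev.evidence = {(b, a): (ba, ab) for (a, b), (ab, ba) in self.evidence.items()}
        return rev

    def partner_of(self, gene_id: int, direction: int = 0) -> int | None:
        """RBH partner of a gene (direction 0: gene in first genome)."""
        if not hasattr(self, "_fwd"):
            self._fwd = {a: b for a, b in self.pairs}
            self._rev = {b: a for a, b in self.pairs}
        return (self._fwd if direction == 0 else self._rev).get(gene_id)


def collect_self_scores(store: HitStore, project: Project) -> dict[int, float]:
    """Self-hit bit scores for every gene, from the stored self contig pairs."""
    scores: dict[int, float] = {}
    for cid in project.contigs:
        if (cid, cid) not in store.index:
            continue
        for h in store.read_chunk((cid, cid)).hits:
            if h.is_self:
                scores[h.query_gene_id] = h.bit_score
    return scores


def compute_srv(
    chunk: GenomeHitChunk,
    self_scores: dict[int, float],
    criteria: OrthologyCriteria = OrthologyCriteria(),
) -> list[ScoredHit]:
    """Annotate a genome hit chunk's hits with SRV and apply the cutoffs.

    Hits with evalue above the ceiling or SRV strictly below the cutoff are
    discarded; queries with no self score are excluded with a warning.
    """
    out: list[ScoredHit] = []
    missing: set[int] = set()
    for h in chunk.hits:
        if h.evalue > criteria.max_evalue:
            continue
        denom = self_scores.get(h.query_gene_id)
        if denom is None or denom <= 0:
            missing.add(h.query_gene_id)
            continue
        srv = h.bit_score / denom
        if srv < criteria.srv_cutoff:
            continue
        out.append(ScoredHit(hit=h, srv=srv))
    if missing:
        logger.warning("chunk %s: %d query genes lack self scores and were excluded",
                       chunk.key, len(missing))
    return out


def best_hits(
    scored: list[ScoredHit],
    criteria: OrthologyCriteria = OrthologyCriteria(),
) -> dict[int, ScoredHit]:
    """Select the single best surviving hit of each query gene."""
    best: dict[int, ScoredHit] = {}
    for sh in scored:
        q = sh.hit.query_gene_id
        if q not in best or sh.sort_key() < best[q].sort_key():
            best[q] = sh
    return best


def reciprocal_match(
    best_ab: dict[int, ScoredHit],
    best_ba: dict[int, ScoredHit],
    genome_pair: tuple[int, int] = (0, 1),
) -> OrthologSet:
    """Match best hits of the two directions into ortholog pairs."""
    result = OrthologSet(genome_pair=genome_pair)
    for a, sh_ab in best_ab.items():
        b = sh_ab.subject
        sh_ba = best_ba.get(b)
        if sh_ba is not None and sh_ba.subject == a:
            result.pairs.add((a, b))
            result.evidence[(a, b)] = (sh_ab, sh_ba)
    return result


def orthologs_for_pair(
    store: HitStore,
    project: Project,
    genome_a: int,
    genome_b: int,
    self_scores: dict[int, float],
    criteria: OrthologyCriteria = OrthologyCriteria(),
) -> OrthologSet:
    """RBH orthologs for one genome pair, straight from the store."""
    ga, gb = project.genomes[genome_a], project.genomes[genome_b]
    chunk_ab = store.merge_genome_chunk(ga, gb)
    chunk_ba = store.merge_genome_chunk(gb, ga)
    best_ab = best_hits(compute_srv(chunk_ab, self_scores, criteria), criteria)
    best_ba = best_hits(compute_srv(chunk_ba, self_scores, criteria), criteria)
    return reciprocal_match(best_ab, best_ba, genome_pair=(genome_a, genome_b))


def orthologs_pairwise(
    project: Project,
    store: HitStore,
    genome_ids: list[int],
    criteria: OrthologyCriteria = OrthologyCriteria(),
    workers: int = 1,
) -> dict[tuple[int, int], OrthologSet]:
    """RBH ortholog sets for every unordered genome pair.

    Pairs are computed independently (optionally in parallel); the result
    is keyed by the ordered pair (a, b) with a < b in ``genome_ids`` order
    and is identical for any worker count. Only ``workers`` genome-pair
    chunk sets are resident at once.
    """
    self_scores = collect_self_scores(store, project)
    pairs = [(a, b) for i, a in enumerate(genome_ids) for b in genome_ids[i + 1:]]

    def one(pair: tuple[int, int]) -> tuple[tuple[int, int], OrthologSet]:
        a, b = pair
        return pair, orthologs_for_pair(store, project, a, b, self_scores, criteria)

    if workers <= 1:
        results = [one(p) for p in pairs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(one, pairs))
    return dict(results)


def ortholog_table(
    ortho: dict[tuple[int, int], OrthologSet], project: Project
) -> pd.DataFrame:
    """Flat TSV-ready table of accepted ortholog pairs with evidence."""
    rows = []
    for (a, b), oset in sorted(ortho.items()):
        name_a = project.genomes[a].name
        name_b = project.genomes[b].name
        for (ga, gb) in sorted(oset.pairs):
            sh_ab, sh_ba = oset.evidence[(ga, gb)]
            rows.append((name_a, ga, name_b, gb,
                         round(sh_ab.srv, 6), round(sh_ba.srv, 6),
                         sh_ab.hit.percent_identity, sh_ba.hit.percent_identity))
    return pd.DataFrame(rows, columns=[
        "genomeA", "geneA", "genomeB", "geneB",
        "srv_ab", "srv_ba", "pid_ab", "pid_ba"])
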