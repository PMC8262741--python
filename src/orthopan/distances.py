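"""Genome similarity matrices: AAI and the percentage of conserved proteins.

POCP between genomes A and B is (C1 + C2) / (T1 + T2) × 100, where Ti is
the number of (active) proteins of genome i and Ci the number of its
proteins conserved in the other genome. Two variants of "conserved" are
offered: the *strict* variant counts a protein conserved if it has at
least one hit with e-value ≤ 1e-5, sequence identity > 50% and alignment
coverage of the query protein > 50% (any qualifying hit, not only best
hits); the *rbh* variant counts a protein conserved if it belongs to a
reciprocal-best-hit ortholog pair under the project's orthology criteria.

AAI between two genomes is the mean over their RBH ortholog pairs of the
average of the two directions' percent identity; it is undefined (reported
as missing, not zero) when the pair shares no orthologs.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import Project
from .hitstore import HitStore
from .orthology import (OrthologSet, OrthologyCriteria, collect_self_scores,
                        orthologs_for_pair)

#: strict-variant thresholds for a conserved protein
POCP_MAX_EVALUE = 1e-5
POCP_MIN_IDENTITY_PCT = 50.0   # strict: identity must exceed this
POCP_MIN_QUERY_COVERAGE_PCT = 50.0  # strict: query coverage must exceed this


@dataclass(frozen=True)
class PocpCriteria:
    """Conserved-protein definition for POCP.

    The strict variant fixes (1e-5, 50, 50) with strict > on identity and
    coverage and inclusive ≤ on the e-value threshold; the rbh variant
    delegates to the RBH orthology criteria instead.
    """

    variant: str = "strict"  # {"strict", "rbh"}
    max_evalue: float = POCP_MAX_EVALUE
    min_identity_pct: float = POCP_MIN_IDENTITY_PCT
    min_query_coverage_pct: float = POCP_MIN_QUERY_COVERAGE_PCT

    def __post_init__(self) -> None:
        if self.variant not in ("strict", "rbh"):
            raise ValueError(f"unknown POCP variant {self.variant!r}")


@dataclass
class SimilarityMatrix:
    genome_order: list[int]
    values: np.ndarray  # symmetric, percent; NaN where undefined
    metric: str

    def to_frame(self, project: Project) -> pd.DataFrame:
        names = [project.genomes[g].name for g in self.genome_order]
        return pd.DataFrame(self.values, index=names, columns=names)

    def to_tsv(self, project: Project, path: str | Path) -> None:
        self.to_frame(project).round(2).to_csv(path, sep="\t")


def _conserved_count_strict(
    store: HitStore, project: Project, query_genome: int, target_genome: int,
    criteria: PocpCriteria,
) -> int:
    chunk = store.merge_genome_chunk(project.genomes[query_genome],
                                     project.genomes[target_genome])
    active = set(project.active_genes(query_genome))
    conserved: set[int] = set()
    for h in chunk.hits:
        if h.query_gene_id not in active:
            continue
        if (h.evalue <= criteria.max_evalue
                and h.percent_identity > criteria.min_identity_pct
                and h.query_coverage_pct > criteria.min_query_coverage_pct):
            conserved.add(h.query_gene_id)
    return len(conserved)


def pocp(
    project: Project,
    store: HitStore,
    genome_a: int,
    genome_b: int,
    criteria: PocpCriteria = PocpCriteria(),
    orthology_criteria: OrthologyCriteria = OrthologyCriteria(),
    ortho: OrthologSet | None = None,
) -> float:
    """Percentage of conserved proteins between two genomes."""
    t1 = len(project.active_genes(genome_a))
    t2 = len(project.active_genes(genome_b))
    if t1 == 0 or t2 == 0:
        raise ValueError("POCP undefined for a genome with no active proteins")
    if genome_a == genome_b:
        # every protein trivially conserved in itself given self-hits
        return 100.0
    if criteria.variant == "strict":
        c1 = _conserved_count_strict(store, project, genome_a, genome_b, criteria)
        c2 = _conserved_count_strict(store, project, genome_b, genome_a, criteria)
    else:
        if ortho is None:
            self_scores = collect_self_scores(store, project)
            ortho = orthologs_for_pair(store, project, genome_a, genome_b,
                                       self_scores, orthology_criteria)
        c1 = c2 = len(ortho.pairs)
    return (c1 + c2) / (t1 + t2) * 100.0


def aai(
    project: Project,
    store: HitStore,
    genome_a: int,
    genome_b: int,
    criteria: OrthologyCriteria = OrthologyCriteria(),
    ortho: OrthologSet | None = None,
) -> float | None:
    """Average amino acid identity over RBH ortholog pairs (bidirectional mean)."""
    if genome_a == genome_b:
        return 100.0
    if ortho is None:
        self_scores = collect_self_scores(store, project)
        ortho = orthologs_for_pair(store, project, genome_a, genome_b,
                                   self_scores, criteria)
    if not ortho.pairs:
        return None
    identities = [
        (ab.hit.percent_identity + ba.hit.percent_identity) / 2.0
        for ab, ba in ortho.evidence.values()
    ]
    return float(np.mean(identities))


def similarity_matrix(
    project: Project,
    store: HitStore,
    genome_ids: Sequence[int],
    metric: str = "aai",
    criteria: OrthologyCriteria = OrthologyCriteria(),
    pocp_criteria: PocpCriteria | None = None,
    workers: int = 1,
) -> SimilarityMatrix:
    """Symmetric all-pairs similarity matrix for one metric.

    Metrics: ``aai``, ``pocp_strict``, ``pocp_rbh``. Pairs are computed
    independently (optionally in parallel); the matrix is symmetric by
    construction with a 100% diagonal.
    """
    if len(genome_ids) < 2:
        raise ValueError("similarity matrix needs at least two genomes")
    if metric not in ("aai", "pocp_strict", "pocp_rbh"):
        raise ValueError(f"unknown metric {metric!r}")
    if pocp_criteria is None:
        pocp_criteria = PocpCriteria(variant="rbh" if metric == "pocp_rbh" else "strict")
    ids = list(genome_ids)
    n = len(ids)
    values = np.full((n, n), 100.0)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    self_scores = collect_self_scores(store, project)

    def one(pair: tuple[int, int]) -> tuple[int, int, float]:
        i, j = pair
        a, b = ids[i], ids[j]
        if metric == "aai":
            val = aai(project, store, a, b, criteria)
            return i, j, np.nan if val is None else val
        ortho = None
        if pocp_criteria.variant == "rbh":
            ortho = orthologs_for_pair(store, project, a, b, self_scores, criteria)
        return i, j, pocp(project, store, a, b, pocp_criteria, criteria, ortho)

    if workers <= 1:
        results = [one(p) for p in pairs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(one, pairs))
    for i, j, val in results:
        values[i, j] = values[j, i] = val
    return SimilarityMatrix(genome_order=ids, values=values, metric=metric)
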