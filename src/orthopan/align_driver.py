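"""All-vs-all alignment orchestration.

Splits the project's active genes into query chunks, runs one alignment
job per chunk (in parallel), and produces a canonical hit stream for the
store. Three backends: an external aligner invoked per chunk through a
command template, a precomputed extended-tabular hit table, and the
synthetic fixture table (a pass-through). The driver never post-filters
scores — it only regroups — so the hit content is exactly what the backend
produced, plus analytically synthesized self-hits where the backend
omitted them (self-hit bit scores are the denominators of score ratio
values downstream).

The final hit stream is re-sorted canonically, so the result is identical
regardless of worker count and job completion order.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

import pandas as pd

from .genome_model import Project
from .hitstore import HitRecord, hits_from_table

logger = logging.getLogger("orthopan")


@dataclass
class AlignmentJob:
    job_id: int
    query_chunk: list[int]  # gene ids
    status: str = "pending"


def plan_jobs(project: Project, chunk_size: int) -> list[AlignmentJob]:
    """Partition active genes into ceil(n/chunk_size) query chunks by gene id."""
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    genes = project.all_active_genes()
    if not genes:
        raise ValueError("empty project: no active genes to align")
    return [
        AlignmentJob(job_id=i, query_chunk=genes[off:off + chunk_size])
        for i, off in enumerate(range(0, len(genes), chunk_size))
    ]


class AlignmentBackend(Protocol):
    def run(self, job: AlignmentJob, project: Project) -> list[HitRecord]: ...


@dataclass
class TableBackend:
    """Precomputed hits in extended BLAST tabular format (file or DataFrame)."""

    table: pd.DataFrame | str | Path
    _hits_by_query: dict[int, list[HitRecord]] = field(default=None, repr=False)

    def _ensure(self) -> None:
        if self._hits_by_query is None:
            by_query: dict[int, list[HitRecord]] = {}
            for hit in hits_from_table(self.table):
                by_query.setdefault(hit.query_gene_id, []).append(hit)
            self._hits_by_query = by_query

    def run(self, job: AlignmentJob, project: Project) -> list[HitRecord]:
        self._ensure()
        out: list[HitRecord] = []
        for gid in job.query_chunk:
            out.extend(self._hits_by_query.get(gid, []))
        return out


class SyntheticBackend(TableBackend):
    """Fixture hit table pass-through (identical mechanics to TableBackend)."""


@dataclass
class ExternalBackend:
    """Run an external aligner per chunk via a command template.

    The template is formatted with ``{query}`` (chunk FASTA), ``{db}``
    (all-project protein FASTA) and ``{out}`` (expected 14-column tabular
    output path), e.g.::

        makeblastdb -in {db} -dbtype prot >/dev/null &&
        blastp -query {query} -db {db} -out {out}
               -outfmt '6 std qlen slen' -evalue 1e-3

    Alignment parameters (matrix, composition-based statistics, ...) live
    in the template, not in this driver.
    """

    cmd_template: str
    workdir: str | Path | None = None

    def run(self, job: AlignmentJob, project: Project) -> list[HitRecord]:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp = Path(tmp)
            query = tmp / f"chunk{job.job_id}.faa"
            db = tmp / "db.faa"
            out = tmp / f"chunk{job.job_id}.tsv"
            with open(query, "w") as fh:
                for gid in job.query_chunk:
                    fh.write(f">{gid}\n{project.genes[gid].protein_seq}\n")
            with open(db, "w") as fh:
                for gid in project.all_active_genes():
                    fh.write(f">{gid}\n{project.genes[gid].protein_seq}\n")
            cmd = self.cmd_template.format(query=shlex.quote(str(query)),
                                           db=shlex.quote(str(db)),
                                           out=shlex.quote(str(out)))
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"alignment job {job.job_id} failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip()[-500:]}")
            if not out.exists():
                return []
            if out.stat().st_size == 0:
                return []
            return hits_from_table(out)


def _run_job(backend: AlignmentBackend, job: AlignmentJob, project: Project) -> list[HitRecord]:
    try:
        hits = backend.run(job, project)
    except Exception as first:
        logger.warning("job %d failed (%s); retrying once", job.job_id, first)
        hits = backend.run(job, project)  # second failure propagates
    job.status = "done"
    return hits


def synthesize_self_hits(
    hits: list[HitRecord], project: Project
) -> tuple[list[HitRecord], int]:
    """Ensure every gene with hits has a self-hit (needed as SRV denominator).

    A missing self-hit is synthesized at 100% identity over the full
    protein length with bit score equal to the gene's maximum observed bit
    score as query. Genes with no hits at all stay absent (they cannot
    take part in score-ratio analyses) and are logged.
    """
    have_self = {h.query_gene_id for h in hits if h.is_self}
    max_bit: dict[int, float] = {}
    for h in hits:
        if h.bit_score > max_bit.get(h.query_gene_id, 0.0):
            max_bit[h.query_gene_id] = h.bit_score
    synthesized: list[HitRecord] = []
    for gid in project.all_active_genes():
        if gid in have_self:
            continue
        if gid not in max_bit:
            logger.warning("gene %d produced no hits; excluded from SRV analyses", gid)
            continue
        n = len(project.genes[gid].protein_seq)
        synthesized.append(HitRecord(
            query_gene_id=gid, subject_gene_id=gid, percent_identity=100.0,
            alignment_length=n, evalue=0.0, bit_score=max_bit[gid],
            query_start=1, query_end=n, subject_start=1, subject_end=n,
            query_length=n, subject_length=n,
        ))
    if synthesized:
        logger.info("synthesized %d missing self-hits", len(synthesized))
    return hits + synthesized, len(synthesized)


def run_all_vs_all(
    project: Project,
    backend: AlignmentBackend,
    workers: int = 1,
    chunk_size: int = 500,
) -> list[HitRecord]:
    """Run every alignment job and return the canonical hit stream.

    Output is invariant to ``workers``: jobs carry a deterministic id and
    the concatenated hits are re-sorted before being handed to the store.
    """
    jobs = plan_jobs(project, chunk_size)
    if workers <= 1:
        results = [_run_job(backend, job, project) for job in jobs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(lambda j: _run_job(backend, j, project), jobs))
    hits: list[HitRecord] = [h for job_hits in results for h in job_hits]
    hits, _ = synthesize_self_hits(hits, project)
    hits.sort(key=lambda h: (h.query_gene_id, h.subject_gene_id, -h.bit_score,
                             -h.percent_identity, h.query_start))
    return hits
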