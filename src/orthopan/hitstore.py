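"""Chunked on-disk storage of all-vs-all protein alignment hits.

Hits are grouped by the contigs of origin of query and subject gene into
*contig hit chunks*, sorted by the (query_contig_id, hit_contig_id) key,
and written to a single data file; the byte position of every chunk goes to
a separate index file so that any chunk can be fetched with one ranged
read. For pairwise-genome operations the contig hit chunks of the two
genomes' contig sets are merged on demand into a *genome hit chunk* — the
memory needed for any pairwise operation is therefore independent of the
number of genomes in the project.

File formats (little-endian throughout)
---------------------------------------
Data file ``<prefix>.ehc``::

    magic b"EHC1" | u16 version=1 | u8 compression (0=none, 1=zlib)
    then per chunk, in lexicographic key order:
    u32 query_contig_id | u32 hit_contig_id | u32 hit_count |
    u32 payload_length | u32 crc32(payload) | payload

The payload is ``hit_count`` fixed-width 72-byte hit records
(``<IIdIddIIIIII``: query_gene, subject_gene, percent_identity,
alignment_length, evalue, bit_score, query_start, query_end,
subject_start, subject_end, query_length, subject_length), optionally
zlib-compressed as one block.

Index file ``<prefix>.ehx``::

    magic b"EHX1" | u16 version=1 | u32 n_entries
    then per entry: u32 query_contig_id | u32 hit_contig_id |
    u64 byte_offset | u64 byte_length | u32 hit_count

``byte_offset``/``byte_length`` span the whole chunk record (header +
payload) in the data file.
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .genome_model import Genome, Project

DATA_MAGIC = b"EHC1"
INDEX_MAGIC = b"EHX1"
VERSION = 1

_HIT = struct.Struct("<IIdIddIIIIII")
_CHUNK_HEADER = struct.Struct("<IIIII")
_DATA_HEADER = struct.Struct("<4sHB")
_INDEX_HEADER = struct.Struct("<4sHI")
_INDEX_ENTRY = struct.Struct("<IIQQI")

#: extended BLAST tabular layout: the 12 standard outfmt-6 columns + qlen + slen
HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein alignment result."""

    query_gene_id: int
    subject_gene_id: int
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_length: int
    subject_length: int

    def pack(self) -> bytes:
        return _HIT.pack(
            self.query_gene_id, self.subject_gene_id, self.percent_identity,
            self.alignment_length, self.evalue, self.bit_score,
            self.query_start, self.query_end, self.subject_start,
            self.subject_end, self.query_length, self.subject_length,
        )

    @classmethod
    def unpack(cls, buf: bytes, offset: int = 0) -> "HitRecord":
        return cls(*_HIT.unpack_from(buf, offset))

    @property
    def query_coverage_pct(self) -> float:
        """Alignment coverage of the query protein, percent."""
        return (self.query_end - self.query_start + 1) / self.query_length * 100.0

    @property
    def is_self(self) -> bool:
        return self.query_gene_id == self.subject_gene_id


def _canonical_hit_sort(h: HitRecord) -> tuple:
    return (h.query_gene_id, -h.bit_score, h.subject_gene_id)


@dataclass
class ContigHitChunk:
    """All hits with query gene on one contig and subject gene on another."""

    key: tuple[int, int]
    hits: list[HitRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class GenomeHitChunk:
    """Merge of the contig hit chunks between two genomes' contig sets."""

    key: tuple[int, int]  # (query_genome_id, hit_genome_id)
    source_keys: set[tuple[int, int]] = field(default_factory=set)
    hits: list[HitRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _check_hit(hit: HitRecord, project: Project) -> None:
    for gid, what in ((hit.query_gene_id, "query"), (hit.subject_gene_id, "subject")):
        if gid not in project.genes:
            raise KeyError(f"unknown {what} gene id {gid} in hit stream")
    for val, name in ((hit.bit_score, "bit_score"), (hit.evalue, "evalue"),
                      (hit.percent_identity, "percent_identity")):
        if math.isnan(val):
            raise ValueError(
                f"NaN {name} for hit {hit.query_gene_id}->{hit.subject_gene_id}")


def write_store(
    hits: Iterable[HitRecord],
    project: Project,
    out_prefix: str | Path,
    compression: bool = True,
) -> tuple[Path, Path]:
    """Group hits into contig hit chunks and write data + index files.

    Chunks are written in lexicographic (query_contig, hit_contig) order;
    within a chunk hits are sorted by (query_gene asc, bit_score desc,
    subject_gene asc) so best-hit scans are single-pass.
    """
    out_prefix = Path(out_prefix)
    grouped: dict[tuple[int, int], list[HitRecord]] = {}
    for hit in hits:
        _check_hit(hit, project)
        key = (project.contig_of_gene(hit.query_gene_id),
               project.contig_of_gene(hit.subject_gene_id))
        grouped.setdefault(key, []).append(hit)

    data_path = out_prefix.parent / (out_prefix.name + ".ehc")
    index_path = out_prefix.parent / (out_prefix.name + ".ehx")
    entries: list[tuple[int, int, int, int, int]] = []
    flag = 1 if compression else 0
    with open(data_path, "wb") as fh:
        fh.write(_DATA_HEADER.pack(DATA_MAGIC, VERSION, flag))
        offset = fh.tell()
        for key in sorted(grouped):
            chunk_hits = sorted(grouped[key], key=_canonical_hit_sort)
            payload = b"".join(h.pack() for h in chunk_hits)
            if compression:
                payload = zlib.compress(payload, 6)
            header = _CHUNK_HEADER.pack(key[0], key[1], len(chunk_hits),
                                        len(payload), zlib.crc32(payload))
            fh.write(header)
            fh.write(payload)
            length = _CHUNK_HEADER.size + len(payload)
            entries.append((key[0], key[1], offset, length, len(chunk_hits)))
            offset += length
    with open(index_path, "wb") as fh:
        fh.write(_INDEX_HEADER.pack(INDEX_MAGIC, VERSION, len(entries)))
        for entry in entries:
            fh.write(_INDEX_ENTRY.pack(*entry))
    return data_path, index_path


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

class HitStore:
    """Read-only view of a written store; one ranged read per chunk access.

    ``access_log`` records every (offset, length) read from the data file,
    which makes the access-locality guarantee testable: a pairwise-genome
    operation touches at most |contigs(A)|·|contigs(B)| byte ranges.
    """

    def __init__(self, prefix: str | Path):
        self.prefix = Path(prefix)
        self.data_path = self.prefix.parent / (self.prefix.name + ".ehc")
        self.index_path = self.prefix.parent / (self.prefix.name + ".ehx")
        self.access_log: list[tuple[int, int]] = []
        with open(self.data_path, "rb") as fh:
            magic, version, flag = _DATA_HEADER.unpack(fh.read(_DATA_HEADER.size))
        if magic != DATA_MAGIC or version != VERSION:
            raise ValueError(f"{self.data_path}: not a hit store (bad magic/version)")
        self.compressed = bool(flag)
        self.index: dict[tuple[int, int], tuple[int, int, int]] = {}
        with open(self.index_path, "rb") as fh:
            magic, version, n = _INDEX_HEADER.unpack(fh.read(_INDEX_HEADER.size))
            if magic != INDEX_MAGIC or version != VERSION:
                raise ValueError(f"{self.index_path}: not a hit store index")
            for _ in range(n):
                qc, hc, off, length, count = _INDEX_ENTRY.unpack(fh.read(_INDEX_ENTRY.size))
                self.index[(qc, hc)] = (off, length, count)

    def __enter__(self) -> "HitStore":
        return self

    def __exit__(self, *exc) -> None:
        pass

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.index)

    def hit_count(self, key: tuple[int, int]) -> int:
        return self.index[key][2] if key in self.index else 0

    def total_hits(self) -> int:
        return sum(v[2] for v in self.index.values())

    def read_chunk(self, key: tuple[int, int]) -> ContigHitChunk:
        """Fetch one contig hit chunk; absent keys yield an empty chunk."""
        if key not in self.index:
            return ContigHitChunk(key=key)
        offset, length, count = self.index[key]
        with open(self.data_path, "rb") as fh:
            fh.seek(offset)
            buf = fh.read(length)
        self.access_log.append((offset, length))
        qc, hc, n, payload_len, crc = _CHUNK_HEADER.unpack_from(buf, 0)
        payload = buf[_CHUNK_HEADER.size:]
        if (qc, hc) != key or len(payload) != payload_len or zlib.crc32(payload) != crc:
            raise ValueError(f"store corrupt at key ({key[0]},{key[1]})")
        if self.compressed:
            payload = zlib.decompress(payload)
        hits = [HitRecord.unpack(payload, i * _HIT.size) for i in range(n)]
        return ContigHitChunk(key=key, hits=hits)

    def merge_genome_chunk(self, query_genome: Genome, hit_genome: Genome) -> GenomeHitChunk:
        """Merge all stored contig pairs (a∈A, b∈B) into one genome hit chunk.

        Example: with A = contigs {1,2} and B = contig {3}, the genome hit
        chunk of A in B draws on contig hit chunks {(1,3),(2,3)} and the
        reverse direction on {(3,1),(3,2)}.
        """
        source_keys = {
            (a, b)
            for a in query_genome.contig_ids
            for b in hit_genome.contig_ids
            if (a, b) in self.index
        }
        hits: list[HitRecord] = []
        for key in sorted(source_keys):
            hits.extend(self.read_chunk(key).hits)
        hits.sort(key=_canonical_hit_sort)
        return GenomeHitChunk(
            key=(query_genome.genome_id, hit_genome.genome_id),
            source_keys=source_keys,
            hits=hits,
        )

    def iter_all_hits(self) -> Iterator[HitRecord]:
        for key in self.keys():
            yield from self.read_chunk(key).hits


# ---------------------------------------------------------------------------
# Extended BLAST tabular I/O
# ---------------------------------------------------------------------------

def hits_from_table(table: pd.DataFrame | str | Path) -> list[HitRecord]:
    """Parse extended BLAST tabular output (outfmt 6 + qlen + slen).

    ``mismatch`` and ``gapopen`` are parsed but not used downstream.
    Query/subject ids must be the project's integer gene ids.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", header=None, names=HIT_TABLE_COLUMNS)
    return [
        HitRecord(
            query_gene_id=int(r.qseqid), subject_gene_id=int(r.sseqid),
            percent_identity=float(r.pident), alignment_length=int(r.length),
            evalue=float(r.evalue), bit_score=float(r.bitscore),
            query_start=int(r.qstart), query_end=int(r.qend),
            subject_start=int(r.sstart), subject_end=int(r.send),
            query_length=int(r.qlen), subject_length=int(r.slen),
        )
        for r in table.itertuples()
    ]


def hits_to_table(hits: Iterable[HitRecord]) -> pd.DataFrame:
    rows = [
        (h.query_gene_id, h.subject_gene_id, h.percent_identity, h.alignment_length,
         0, 0, h.query_start, h.query_end, h.subject_start, h.subject_end,
         h.evalue, h.bit_score, h.query_length, h.subject_length)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)
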