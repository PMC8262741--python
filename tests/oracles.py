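"""Independent brute-force oracles for the test suite.

Everything here works on a *flat* hit table (list of HitRecord) plus a
gene→genome mapping, with plain dict/loop code and no chunking, no store
and no reuse of the package's orthology/geneset internals — so it can
serve as the reference the chunked pipeline is checked against.
"""

from __future__ import annotations

from orthopan.hitstore import HitRecord


def self_bits(hits: list[HitRecord]) -> dict[int, float]:
    out: dict[int, float] = {}
    for h in hits:
        if h.query_gene_id == h.subject_gene_id:
            out[h.query_gene_id] = max(out.get(h.query_gene_id, 0.0), h.bit_score)
    return out


def brute_best_hits(
    hits: list[HitRecord],
    genome_of: dict[int, int],
    query_genome: int,
    target_genome: int,
    srv_cutoff: float = 0.3,
    max_evalue: float = 1e-10,
) -> dict[int, HitRecord]:
    """Best surviving hit of each gene of one genome into another, by full scan."""
    selfs = self_bits(hits)
    best: dict[int, tuple] = {}
    for h in hits:
        q, s = h.query_gene_id, h.subject_gene_id
        if genome_of.get(q) != query_genome or genome_of.get(s) != target_genome:
            continue
        if h.evalue > max_evalue or q not in selfs or selfs[q] <= 0:
            continue
        srv = h.bit_score / selfs[q]
        if srv < srv_cutoff:
            continue
        key = (-srv, -h.bit_score, -h.percent_identity, s)
        if q not in best or key < best[q][0]:
            best[q] = (key, h)
    return {q: h for q, (key, h) in best.items()}


def brute_rbh(
    hits: list[HitRecord],
    genome_of: dict[int, int],
    genome_a: int,
    genome_b: int,
    srv_cutoff: float = 0.3,
    max_evalue: float = 1e-10,
) -> set[tuple[int, int]]:
    fwd = brute_best_hits(hits, genome_of, genome_a, genome_b, srv_cutoff, max_evalue)
    rev = brute_best_hits(hits, genome_of, genome_b, genome_a, srv_cutoff, max_evalue)
    return {
        (a, h.subject_gene_id)
        for a, h in fwd.items()
        if h.subject_gene_id in rev and rev[h.subject_gene_id].subject_gene_id == a
    }


def brute_all_rbh(
    hits: list[HitRecord],
    genome_of: dict[int, int],
    genome_ids: list[int],
    srv_cutoff: float = 0.3,
    max_evalue: float = 1e-10,
) -> dict[tuple[int, int], set[tuple[int, int]]]:
    return {
        (a, b): brute_rbh(hits, genome_of, a, b, srv_cutoff, max_evalue)
        for i, a in enumerate(genome_ids)
        for b in genome_ids[i + 1:]
    }


def brute_pan_clusters(
    active_by_genome: dict[int, list[int]],
    order: list[int],
    rbh: dict[tuple[int, int], set[tuple[int, int]]],
) -> list[dict[int, int]]:
    """Reference-seeded iterative clustering recomputed with plain loops.

    Same founder rule as the pipeline: a gene joins the lowest-index
    cluster whose founder it is RBH-paired with, else founds a new one.
    """

    def partner(fa: int, fb: int, gene: int) -> int | None:
        if (fa, fb) in rbh:
            for x, y in rbh[(fa, fb)]:
                if x == gene:
                    return y
        if (fb, fa) in rbh:
            for y, x in rbh[(fb, fa)]:
                if x == gene:
                    return y
        return None

    clusters: list[dict[int, int]] = [
        {order[0]: gid} for gid in active_by_genome[order[0]]
    ]
    founders: list[tuple[int, int]] = [
        (order[0], gid) for gid in active_by_genome[order[0]]
    ]
    for genome in order[1:]:
        taken: set[int] = set()
        for gid in active_by_genome[genome]:
            joined = False
            for idx, (fg, fgid) in enumerate(founders):
                if genome in clusters[idx]:
                    continue
                p = partner(fg, genome, fgid)
                if p == gid and gid not in taken:
                    clusters[idx][genome] = gid
                    taken.add(gid)
                    joined = True
                    break
            if not joined:
                clusters.append({genome: gid})
                founders.append((genome, gid))
    return clusters


def brute_counts(clusters: list[dict[int, int]], genome_ids: list[int]) -> dict:
    sel = set(genome_ids)
    pan = len(clusters)
    core = sum(1 for c in clusters if sel <= c.keys())
    singles = {g: 0 for g in genome_ids}
    for c in clusters:
        if len(c) == 1:
            singles[next(iter(c))] += 1
    return {"pan": pan, "core": core, "singletons": singles}


def brute_signatures(clusters: list[dict[int, int]]) -> dict[frozenset[int], int]:
    out: dict[frozenset[int], int] = {}
    for c in clusters:
        sig = frozenset(c)
        out[sig] = out.get(sig, 0) + 1
    return out


def brute_aai(
    hits: list[HitRecord],
    genome_of: dict[int, int],
    genome_a: int,
    genome_b: int,
    srv_cutoff: float = 0.3,
    max_evalue: float = 1e-10,
) -> float | None:
    """Mean bidirectional identity over RBH pairs, from the flat table."""
    fwd = brute_best_hits(hits, genome_of, genome_a, genome_b, srv_cutoff, max_evalue)
    rev = brute_best_hits(hits, genome_of, genome_b, genome_a, srv_cutoff, max_evalue)
    pairs = brute_rbh(hits, genome_of, genome_a, genome_b, srv_cutoff, max_evalue)
    if not pairs:
        return None
    vals = [
        (fwd[a].percent_identity + rev[b].percent_identity) / 2.0
        for a, b in pairs
    ]
    return sum(vals) / len(vals)


def brute_pocp_strict(
    hits: list[HitRecord],
    genome_of: dict[int, int],
    active_by_genome: dict[int, list[int]],
    genome_a: int,
    genome_b: int,
) -> float:
    """POCP by direct double count over the flat table (Qin-style thresholds)."""

    def conserved(qg: int, sg: int) -> int:
        ok: set[int] = set()
        active = set(active_by_genome[qg])
        for h in hits:
            if h.query_gene_id not in active or genome_of.get(h.subject_gene_id) != sg:
                continue
            cov = (h.query_end - h.query_start + 1) / h.query_length * 100.0
            if h.evalue <= 1e-5 and h.percent_identity > 50.0 and cov > 50.0:
                ok.add(h.query_gene_id)
        return len(ok)

    t1, t2 = len(active_by_genome[genome_a]), len(active_by_genome[genome_b])
    c1 = conserved(genome_a, genome_b)
    c2 = conserved(genome_b, genome_a)
    return (c1 + c2) / (t1 + t2) * 100.0
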