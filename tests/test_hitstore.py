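"""Chunked store: grouping, indexing, round-trip fidelity, genome merge."""

import struct
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

import orthopan as op
from orthopan.hitstore import HitRecord, HitStore, write_store

from conftest import make_hit, make_project, self_hit


@pytest.fixture
def figure1_project():
    """Genome A = contigs {1,2}, B = contig {3}, C = contig {4}; 2 genes each."""
    return make_project(
        genes_per_contig={1: 2, 2: 2, 3: 2, 4: 2},
        genome_contigs=[{1, 2}, {3}, {4}],
    )


def _store(tmp_path, hits, project, **kw):
    prefix = tmp_path / "hits"
    write_store(hits, project, prefix, **kw)
    return HitStore(prefix)


class TestWriteRead:
    def test_grouping_into_chunks(self, tmp_path, figure1_project):
        # genes 0,1 on contig 1; 2,3 on contig 2; 4,5 on contig 3
        hits = [
            make_hit(0, 4, 100), make_hit(0, 5, 90), make_hit(1, 4, 80),  # (1,3)
            make_hit(2, 4, 70), make_hit(3, 5, 60),                       # (2,3)
            make_hit(4, 0, 100),                                          # (3,1)
        ]
        store = _store(tmp_path, hits, figure1_project)
        assert store.keys() == [(1, 3), (2, 3), (3, 1)]
        assert [store.hit_count(k) for k in store.keys()] == [3, 2, 1]

    def test_empty_stream(self, tmp_path, figure1_project):
        store = _store(tmp_path, [], figure1_project)
        assert store.keys() == []
        assert store.total_hits() == 0
        assert len(store.read_chunk((1, 3))) == 0

    def test_within_chunk_canonical_sort(self, tmp_path, figure1_project):
        hits = [make_hit(1, 4, 50), make_hit(0, 5, 90), make_hit(0, 4, 120),
                make_hit(0, 6, 90)]  # gene 6 is on contig 4 -> different chunk
        store = _store(tmp_path, hits, figure1_project)
        chunk = store.read_chunk((1, 3))
        order = [(h.query_gene_id, h.bit_score) for h in chunk.hits]
        assert order == [(0, 120.0), (0, 90.0), (1, 50.0)]

    def test_absent_key_empty_chunk(self, tmp_path, figure1_project):
        store = _store(tmp_path, [make_hit(0, 4, 50)], figure1_project)
        assert store.read_chunk((2, 4)).hits == []

    def test_self_contig_pair_holds_self_hits(self, tmp_path, figure1_project):
        hits = [self_hit(0), self_hit(1), make_hit(0, 1, 150)]
        store = _store(tmp_path, hits, figure1_project)
        chunk = store.read_chunk((1, 1))
        assert len(chunk) == 3
        assert sum(h.is_self for h in chunk.hits) == 2

    def test_unknown_gene_id_errors(self, tmp_path, figure1_project):
        with pytest.raises(KeyError, match="99"):
            _store(tmp_path, [make_hit(0, 99, 50)], figure1_project)

    def test_nan_score_errors(self, tmp_path, figure1_project):
        with pytest.raises(ValueError, match="NaN"):
            _store(tmp_path, [make_hit(0, 4, float("nan"))], figure1_project)

    def test_corruption_detected(self, tmp_path, figure1_project):
        store = _store(tmp_path, [make_hit(0, 4, 50)], figure1_project)
        offset, length, _ = store.index[(1, 3)]
        with open(store.data_path, "r+b") as fh:
            fh.seek(offset + length - 1)
            byte = fh.read(1)
            fh.seek(offset + length - 1)
            fh.write(bytes([byte[0] ^ 0xFF]))
        fresh = HitStore(tmp_path / "hits")
        with pytest.raises(ValueError, match=r"corrupt at key \(1,3\)"):
            fresh.read_chunk((1, 3))

    @pytest.mark.parametrize("compression", [True, False])
    def test_round_trip_identity(self, tmp_path, figure1_project, compression):
        hits = [self_hit(g) for g in range(8)] + [
            make_hit(0, 4, 100), make_hit(0, 4, 100),  # duplicate rows preserved
            make_hit(5, 2, 77.5, pident=63.2, evalue=3e-20),
        ]
        store = _store(tmp_path, hits, figure1_project, compression=compression)
        assert Counter(store.iter_all_hits()) == Counter(hits)


hit_strategy = st.builds(
    HitRecord,
    query_gene_id=st.integers(0, 7),
    subject_gene_id=st.integers(0, 7),
    percent_identity=st.floats(0, 100, allow_nan=False),
    alignment_length=st.integers(1, 500),
    evalue=st.floats(0, 1, allow_nan=False),
    bit_score=st.floats(0.1, 5000, allow_nan=False),
    query_start=st.just(1),
    query_end=st.integers(1, 100),
    subject_start=st.just(1),
    subject_end=st.integers(1, 100),
    query_length=st.just(100),
    subject_length=st.just(100),
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(hits=st.lists(hit_strategy, max_size=60))
def test_round_trip_property(tmp_path_factory, hits):
    """write_store then read over all keys is the identity on the hit multiset."""
    project = make_project({1: 2, 2: 2, 3: 2, 4: 2}, [{1, 2}, {3}, {4}])
    tmp = tmp_path_factory.mktemp("rt")
    store = _store(tmp, hits, project)
    assert Counter(store.iter_all_hits()) == Counter(hits)
    # index completeness: keys = distinct contig pairs of the input
    expected_keys = {
        (project.contig_of_gene(h.query_gene_id),
         project.contig_of_gene(h.subject_gene_id)) for h in hits
    }
    assert set(store.index) == expected_keys
    assert store.total_hits() == len(hits)


class TestGenomeMerge:
    def test_forward_merge_keys(self, tmp_path, figure1_project):
        """A={1,2} vs B={3}: source chunks exactly {(1,3),(2,3)}."""
        hits = [make_hit(0, 4, 100), make_hit(2, 5, 90), make_hit(4, 0, 80),
                make_hit(4, 2, 70)]
        store = _store(tmp_path, hits, figure1_project)
        a, b = figure1_project.genomes[0], figure1_project.genomes[1]
        merged = store.merge_genome_chunk(a, b)
        assert merged.source_keys == {(1, 3), (2, 3)}
        assert len(merged) == 2

    def test_reverse_merge_keys(self, tmp_path, figure1_project):
        """B={3} vs A={1,2}: source chunks exactly {(3,1),(3,2)}."""
        hits = [make_hit(0, 4, 100), make_hit(2, 5, 90), make_hit(4, 0, 80),
                make_hit(4, 2, 70)]
        store = _store(tmp_path, hits, figure1_project)
        a, b = figure1_project.genomes[0], figure1_project.genomes[1]
        merged = store.merge_genome_chunk(b, a)
        assert merged.source_keys == {(3, 1), (3, 2)}
        assert [h.query_gene_id for h in merged.hits] == [4, 4]

    def test_no_hits_between_genomes(self, tmp_path, figure1_project):
        store = _store(tmp_path, [make_hit(0, 4, 100)], figure1_project)
        merged = store.merge_genome_chunk(figure1_project.genomes[0],
                                          figure1_project.genomes[2])
        assert merged.source_keys == set()
        assert merged.hits == []

    def test_merge_resorted_by_query_then_score(self, tmp_path, figure1_project):
        hits = [make_hit(2, 4, 300), make_hit(0, 4, 100), make_hit(0, 5, 200)]
        store = _store(tmp_path, hits, figure1_project)
        merged = store.merge_genome_chunk(figure1_project.genomes[0],
                                          figure1_project.genomes[1])
        assert [(h.query_gene_id, h.bit_score) for h in merged.hits] == \
            [(0, 200.0), (0, 100.0), (2, 300.0)]

    def test_access_locality_bound(self, tmp_path, figure1_project):
        """A pairwise merge performs at most |contigs(A)|*|contigs(B)| ranged reads."""
        hits = [make_hit(q, s, 50 + q) for q in range(4) for s in (4, 5)]
        store = _store(tmp_path, hits, figure1_project)
        store.access_log.clear()
        a, b = figure1_project.genomes[0], figure1_project.genomes[1]
        store.merge_genome_chunk(a, b)
        assert len(store.access_log) <= len(a.contig_ids) * len(b.contig_ids)
        # each access is one contiguous indexed range
        assert set(store.access_log) <= {(o, l) for o, l, _ in store.index.values()}


def test_header_layout(tmp_path, figure1_project):
    """Data file opens with magic, version and compression flag as documented."""
    store = _store(tmp_path, [make_hit(0, 4, 50)], figure1_project, compression=False)
    raw = store.data_path.read_bytes()
    magic, version, flag = struct.unpack("<4sHB", raw[:7])
    assert (magic, version, flag) == (b"EHC1", 1, 0)
    assert store.index_path.read_bytes()[:4] == b"EHX1"
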