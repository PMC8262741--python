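"""Pan/core/singleton partitioning, Venn/UpSet tables, accumulation curves."""

import itertools
import json

import numpy as np
import pytest

import orthopan as op
from orthopan.genesets import (development_curves, development_sizes,
                               pan_genome, reference_ortholog_table,
                               singletons, upset_table, venn_regions)
from orthopan.orthology import orthologs_pairwise

import oracles


@pytest.fixture(scope="module")
def fx_env(tmp_path_factory):
    fx = op.generate(op.FixtureSpec(seed=11))
    prefix = tmp_path_factory.mktemp("gs") / "hits"
    op.write_store(fx.hits, fx.project, prefix)
    store = op.HitStore(prefix)
    ids = [g.genome_id for g in fx.project.genomes]
    ortho = orthologs_pairwise(fx.project, store, ids)
    return fx, store, ids, ortho


class TestPanGenome:
    def test_planted_counts_recovered(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        expected = fx.truth.expected_counts(ids)
        assert pm.pan_size == expected["pan"]
        assert pm.core_size == expected["core"]
        assert int(pm.singleton_mask.sum()) == sum(expected["singletons"].values())

    def test_single_genome_all_singletons(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, [0], 0, ortho=ortho)
        n = len(fx.project.active_genes(0))
        assert pm.pan_size == n
        assert pm.core_size == n  # trivially core of a one-genome set
        assert int(pm.singleton_mask.sum()) == n

    def test_disjoint_genomes_pan_is_sum(self, fx_env):
        fx, store, ids, _ = fx_env
        # no-ortholog situation emulated with an impossible cutoff
        crit = op.OrthologyCriteria(srv_cutoff=1.01)
        pm = pan_genome(fx.project, ids[:2], ids[0], crit, store=store)
        assert pm.pan_size == (len(fx.project.active_genes(ids[0]))
                               + len(fx.project.active_genes(ids[1])))
        assert pm.core_size == 0

    def test_reference_not_in_set_errors(self, fx_env):
        fx, _, ids, ortho = fx_env
        with pytest.raises(ValueError, match="reference"):
            pan_genome(fx.project, ids[:2], 3, ortho=ortho)

    def test_partition_identity(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, 0, ortho=ortho)
        weights = pm.presence.sum(axis=1)
        assert pm.core_size + int((weights < len(ids)).sum()) == pm.pan_size
        # membership conservation: every active gene in exactly one cluster
        members = [gid for c in pm.clusters for gid in c.members.values()]
        assert sorted(members) == fx.project.all_active_genes()

    def test_core_size_reference_independent_on_clean_data(self, fx_env):
        fx, _, ids, ortho = fx_env
        sizes = {pan_genome(fx.project, ids, r, ortho=ortho).core_size for r in ids}
        assert len(sizes) == 1

    def test_matches_brute_force_oracle(self, fx_env):
        fx, _, ids, ortho = fx_env
        rbh = {k: set(v.pairs) for k, v in ortho.items()}
        active = {g: fx.project.active_genes(g) for g in ids}
        clusters = oracles.brute_pan_clusters(active, ids, rbh)
        expected = oracles.brute_counts(clusters, ids)
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        assert pm.pan_size == expected["pan"]
        assert pm.core_size == expected["core"]


class TestCoreAndSingletons:
    def test_core_monotone_under_genome_addition(self, fx_env):
        fx, _, ids, ortho = fx_env
        sizes = [pan_genome(fx.project, ids[:k], ids[0], ortho=ortho).core_size
                 for k in range(1, len(ids) + 1)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_singletons_per_genome(self, fx_env):
        fx, _, ids, ortho = fx_env
        singles = singletons(fx.project, ids, ortho=ortho)
        expected = fx.truth.expected_counts(ids)["singletons"]
        assert {g: len(v) for g, v in singles.items()} == expected

    def test_identical_genome_copies_all_core(self, tmp_path):
        fx = op.generate(op.FixtureSpec(seed=4, n_genomes=3, n_core=20,
                                        n_accessory=0, singletons_per_genome=0,
                                        identity_base=100.0))
        prefix = tmp_path / "h"
        op.write_store(fx.hits, fx.project, prefix)
        store = op.HitStore(prefix)
        ids = [0, 1, 2]
        pm = pan_genome(fx.project, ids, 0, store=store)
        assert pm.pan_size == pm.core_size == 20


class TestVenn:
    def test_two_genomes_three_regions_sum_to_pan(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids[:2], ids[0], ortho=ortho)
        table = venn_regions(pm, ids[:2])
        assert len(table.rows) == 3
        assert sum(c for _, c in table.rows) == pm.pan_size

    def test_all_regions_emitted_including_zero(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        table = venn_regions(pm, ids)
        assert len(table.rows) == 2 ** len(ids) - 1

    def test_six_genomes_rejected(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        with pytest.raises(ValueError, match="five sets"):
            venn_regions(pm, [0, 1, 2, 3, 0, 1])

    def test_counts_equal_brute_force_signature_tally(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        truth_sigs = oracles.brute_signatures(
            [dict(c.members) for c in pm.clusters])
        table = venn_regions(pm, ids)
        for sig, count in table.rows:
            assert count == truth_sigs.get(sig, 0)


class TestUpset:
    def test_default_sort_counts_non_increasing(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        counts = [c for _, c in upset_table(pm).rows]
        assert counts == sorted(counts, reverse=True)

    def test_degree_sort_groups_by_signature_size(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        degrees = [len(sig) for sig, _ in upset_table(pm, sort="degree").rows]
        assert degrees == sorted(degrees)

    def test_only_observed_signatures(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        table = upset_table(pm)
        assert all(count > 0 for _, count in table.rows)
        assert sum(c for _, c in table.rows) == pm.pan_size
        truth_sigs = oracles.brute_signatures([dict(c.members) for c in pm.clusters])
        assert dict(table.rows) == truth_sigs

    def test_deviation_sort_and_unknown_key(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        rows = upset_table(pm, sort="deviation").rows
        assert len(rows) == len(upset_table(pm).rows)
        with pytest.raises(ValueError, match="sort"):
            upset_table(pm, sort="alphabetical")

    def test_json_schema(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        doc = json.loads(upset_table(pm).to_json(fx.project, ids))
        assert set(doc) == {"sets", "intersections"}
        assert all({"signature", "degree", "count"} <= set(row)
                   for row in doc["intersections"])


class TestDevelopmentCurves:
    def test_first_point_is_first_genome(self, fx_env):
        fx, _, ids, ortho = fx_env
        df = development_curves(fx.project, ids, ortho=ortho, n_permutations=1)
        n0 = len(fx.project.active_genes(ids[0]))
        assert df.loc[df.k == 1, "pan_median"].item() == n0
        assert df.loc[df.k == 1, "core_median"].item() == n0

    def test_monotone_for_every_permutation(self, fx_env):
        fx, _, ids, ortho = fx_env
        for order in itertools.permutations(ids):
            df = development_sizes(fx.project, list(order), ortho)
            assert df["pan"].is_monotonic_increasing
            assert (df["core"].diff().dropna() <= 0).all()

    def test_exhaustive_three_genome_permutations_match_brute_force(self, fx_env):
        fx, _, ids, ortho = fx_env
        rbh = {k: set(v.pairs) for k, v in ortho.items()}
        active = {g: fx.project.active_genes(g) for g in ids}
        for order in itertools.permutations(ids[:3]):
            df = development_sizes(fx.project, list(order), ortho)
            for k in range(1, 4):
                clusters = oracles.brute_pan_clusters(active, list(order[:k]), rbh)
                expected = oracles.brute_counts(clusters, list(order[:k]))
                row = df[df.k == k].iloc[0]
                assert (row["pan"], row["core"]) == (expected["pan"], expected["core"])

    def test_seeded_quantiles_reproducible(self, fx_env):
        fx, _, ids, ortho = fx_env
        a = development_curves(fx.project, ids, ortho=ortho, n_permutations=5, seed=9)
        b = development_curves(fx.project, ids, ortho=ortho, n_permutations=5, seed=9)
        assert a.equals(b)


class TestReferenceTable:
    def test_row_count_and_core_flags(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, ids, ids[0], ortho=ortho)
        df = reference_ortholog_table(pm, fx.project, ids[0])
        assert len(df) == len(fx.project.active_genes(ids[0]))
        core_genes = {c.members[ids[0]]
                      for m in [fx.truth.expected_counts(ids)]
                      for c, ok in zip(pm.clusters, pm.core_mask)
                      if ok and ids[0] in c.members}
        assert set(df.loc[df.core == 1, "gene_id"]) == core_genes
        # planted truth: core flags match clusters spanning all genomes
        planted_core_ref = {m[ids[0]] for m in fx.truth.clusters
                            if set(ids) <= set(m)}
        assert set(df.loc[df.core == 1, "gene_id"]) == planted_core_ref

    def test_single_genome_project_all_core(self, fx_env):
        fx, _, ids, ortho = fx_env
        pm = pan_genome(fx.project, [0], 0, ortho=ortho)
        df = reference_ortholog_table(pm, fx.project, 0)
        assert (df.core == 1).all()
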