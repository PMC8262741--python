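# orthopan

Comparative gene-content analysis for sets of microbial genomes:
reciprocal-best-hit (RBH) orthology computed on a chunked, byte-indexed
on-disk store of all-vs-all protein alignment hits, with the standard
downstream analytics — pan/core/singleton partitioning, Venn and UpSet
intersection tables, accumulation curves, and AAI / POCP similarity
matrices.

It is written for microbiologists and bioinformaticians who have a handful
to a few hundred annotated genomes (GenBank flat files or protein FASTA)
and want differential gene content and phylogenomic distance proxies
without a database server: all state lives in plain files.

## Method

Genes are compared by all-against-all protein alignment (BLASTP or any
tool emitting the extended 14-column tabular format). Hits are grouped by
the contigs of origin of query and subject gene into *contig hit chunks*,
stored consecutively in one data file, and indexed by byte position under
the key `(query_contig_id, hit_contig_id)`. A genome is a set of 1..*n*
contigs; for a genome pair (A, B) the chunks of A×B are merged on demand
into a *genome hit chunk*, so the memory needed for any pairwise operation
is independent of the number of genomes in the project.

Within a genome hit chunk, each hit is scored with the **score ratio value**

    SRV(q → s) = bitscore(q → s) / bitscore(q → q)

which normalizes bit scores to (0, 1] via the query's self-hit. Hits with
e-value above a ceiling (default 1e-10) or SRV below a cutoff (default
0.3) are discarded; the best hit of every query gene maximizes SRV, with
bit score and percent identity as secondary criteria and the lowest
subject gene id as the final deterministic tie-break. Genes whose best
hits point at each other in both directions are accepted as **orthologs**.

Pan-genome clustering is reference-seeded and iterative: every gene of the
reference founds a cluster; genes of subsequent genomes join the cluster
whose founder they are RBH-paired with, or found new clusters. The
resulting clusters × genomes presence/absence matrix yields the core
genome (all-true rows), singletons (weight-one rows), Venn regions (≤ 5
genomes), UpSet intersection tables and accumulation curves.

Distance metrics: **AAI** is the mean over RBH pairs of the bidirectional
percent identity; **POCP** is `(C1 + C2) / (T1 + T2) × 100` with `Ti` the
protein count of genome *i* and `Ci` its proteins conserved in the other
genome — either any hit with e-value ≤ 1e-5, identity > 50% and query
coverage > 50% (`strict` variant) or RBH-ortholog membership (`rbh`
variant).

Identical paralogs (byte-identical proteins within one genome) are
collapsed at project setup; the lowest-id copy represents the group.

## Worked example

Generate a synthetic 4-genome project with planted truth, then run the
full pipeline:

```
orthopan fixtures --seed 42 --out data
cat > config.yaml <<EOF
name: demo
genomes:
  - {path: data/G0.gbk, name: G0}
  - {path: data/G1.gbk, name: G1}
  - {path: data/G2.gbk, name: G2}
  - {path: data/G3.gbk, name: G3}
outdir: out
backend: synthetic
hits_table: data/hits.tsv
EOF
orthopan init config.yaml     # initialized demo: 4 genomes, 162 active genes
orthopan align config.yaml    # stored 1036 hits in 41 chunks
orthopan run config.yaml
```

The final command prints:

```json
{
  "genomes": 4,
  "genes": 162,
  "active_genes": 162,
  "stored_hits": 1036,
  "ortholog_pairs": 202,
  "pan": 56,
  "core": 30,
  "singletons": {"G0": 4, "G1": 4, "G2": 4, "G3": 4}
}
```

The pan genome has 56 gene clusters, of which 30 are core (present in all
four genomes) and 16 are singletons (4 private genes per genome) — exactly
the planted composition of the fixture (30 core + 10 accessory + 4×4
singleton clusters). `orthopan aai config.yaml` prints the AAI matrix —
80.0% between every genome pair here, the identity level the generator
planted for cluster mates:

```
genome  G0      G1      G2      G3
G0      100.0   80.0    80.0    80.0
G1      80.0    100.0   80.0    80.0
...
```

`orthopan upset config.yaml` lists intersection signatures sorted by
cluster count (the 30-cluster four-genome core first), and
`orthopan orthologs config.yaml` emits the accepted RBH pairs with their
SRV and identity evidence in both directions. For real data, set
`backend: external` with a `cmd_template` invoking your aligner, e.g.

```
cmd_template: "makeblastdb -in {db} -dbtype prot -logfile /dev/null &&
  blastp -query {query} -db {db} -out {out} -outfmt '6 std qlen slen' -evalue 1e-3"
```

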