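# Methods

## Data model and ingestion

A project holds genomes, each a non-empty set of contigs; a contig holds
genes ordered by start coordinate; gene, contig and genome ids are dense
integers assigned in ingestion order, so a project is fully reproducible
from its input files and the TSV manifests it writes. GenBank ingestion
takes the `/translation` qualifier verbatim when present; a CDS without
one is translated from its nucleotide span with the standard code
(trailing stop removed), and compound (`join(...)`) CDS without a
translation are skipped with a warning rather than spliced — such features
are almost always pseudogenes and splicing logic is irrelevant to
protein-level orthology. FASTA-only input has no coordinates; the 0/0
sentinel with strand `+` marks that explicitly.

Identical-paralog filtering collapses byte-identical protein sequences
genome-wide (across all contigs of a genome), keeping the copy with the
lowest gene id — first in locus order — and recording removed ids as
aliases. The operation is idempotent, and every downstream count uses
active (unaliased) genes only. Filtering is genome-wide rather than
per-contig because identical copies on different replicons are still the
same protein for gene-content purposes.

## Hit store

One data file plus one index file per project. Hits are grouped by
`(query_contig_id, hit_contig_id)`, chunks written in lexicographic key
order, each length-prefixed and CRC-checksummed, with optional per-chunk
zlib block compression (flag in the header); the index maps each key to
`(byte_offset, byte_length, hit_count)`. The exact byte layout is
documented in `hitstore.py`. Within a chunk, hits are sorted by
(query gene asc, bit score desc, subject gene asc) so best-hit scans are
single-pass and deterministic; the chunk-level sort order is what makes
genome-pair access a handful of contiguous ranged reads. Self-pairs
(a gene against itself) are stored: they are the SRV denominators.
`hit_count` is cached in the index so summary statistics need no data-file
reads. The testable form of the scalability claim is access locality: any
pairwise-genome operation performs at most |contigs(A)|·|contigs(B)|
ranged reads, asserted against the store's access log.

## Alignment driver

Queries are split into chunks of `chunk_size` genes (default 500) in gene
id order and run per chunk, optionally in parallel threads. Backends:
`external` (a shell command template with `{query}`, `{db}`, `{out}`
placeholders, expecting 14-column extended tabular output), `table`
(precomputed hits) and `synthetic` (fixture table). The driver never
filters scores — it only regroups — so the stored hits are exactly what
the aligner produced. Jobs are retried once; the second failure
propagates. Because the concatenated hit stream is canonically re-sorted
before storage, store files are byte-identical for any worker count.

Missing self-hits are synthesized at 100% identity and full length with
bit score equal to the gene's maximum observed bit score as query (an
aligner can drop self-hits under composition-based statistics); a gene
with no hits at all is excluded from SRV-based analyses with a warning.

## Orthology

Acceptance thresholds: e-value ≤ `max_evalue` (default 1e-10) and
SRV ≥ `srv_cutoff` (default 0.3; a hit exactly at the cutoff is kept —
the boundary is unit-tested). The 0.3 default is a conventional
conservative choice; per-project automatic cutoff estimation from the SRV
histogram is deliberately out of scope, with the criteria object as the
hook. Best hits maximize (SRV, bit score, percent identity, −subject id).
With exact SRV arithmetic the bit-score criterion cannot differ from SRV
within one query gene (the denominator is fixed); it is kept in the
sequence for fidelity and for robustness if SRV is ever rounded. The
lowest-subject-id tie-break makes results schedule-independent. Pairwise
genome computations are independent and parallelizable; at most `workers`
genome-pair chunk sets are resident at once.

## Gene sets

Clustering is reference-seeded and iterative, joining genes to cluster
*founders* only — no transitive closure. A gene RBH-paired with a
non-founder member but not with any founder founds a new cluster. This
keeps the computation pairwise and streamable and is order-dependent on
noisy data (documented behaviour of the iterative method; MCL-style
clusterers behave differently). On clean data the core/pan *sizes* are
reference-independent, which is tested. When a gene is RBH-paired with
founders in several genomes, the lowest-id (earliest-founded) cluster
wins — a deterministic rule for a case the pairwise matchings cannot
arbitrate.

Venn output (2–5 genomes) emits all 2^n − 1 regions including zero
counts; UpSet emits only observed signatures, sorted by cardinality
(default), degree, or deviation — observed count minus the expectation
under independent per-genome presence frequencies. Accumulation curves
use `n_permutations` seeded genome orderings (default 10; permutation 0
is always the input order) and report median and quartiles of
pan/core/singleton size per prefix length. Counts are of clusters, not
genes, so Venn regions sum exactly to the pan size.

## Distances

AAI: mean over RBH pairs of the average of the two directions' percent
identity; undefined (missing, not 0) without pairs. POCP strict variant:
a protein is conserved if *any* hit into the partner genome has e-value
≤ 1e-5, identity > 50% and query coverage > 50% — identity and coverage
strictly greater-than, the e-value threshold inclusive; coverage is
`(query_end − query_start + 1) / query_length × 100`. The rbh variant
counts RBH-ortholog membership instead. Matrices are symmetric by
construction with a 100% diagonal. Whole-genome nucleotide identity is
computed by external tools and is not implemented; its 200-genome
on-the-fly cap is retained as the config constant `FASTANI_MAX_GENOMES`
for API parity.

## Synthetic fixtures

The generator plants: core clusters (all genomes), accessory clusters
(membership drawn per genome at `accessory_presence_prob`, redrawn until
2 ≤ size ≤ n−1 so planted core/singleton counts are exact), and
`singletons_per_genome` private genes; optional identical duplicate loci
at `identical_paralog_rate`. Default conditions: 4 genomes, 1–3 contigs
each, 30 core + 10 accessory clusters, 4 singletons per genome, 80%
cluster-mate identity, zero score noise. Proteins are random 100–240 aa
strings; cluster mates are seeded point-substitution variants at the
target identity, so a real aligner run on the emitted files is
qualitatively consistent with the planted table.

The planted hit table carries self-hits at 2 bits/residue (the maximal
bit score for a full-length self alignment under a BLOSUM-like scoring
regime), within-cluster hits with bit ∝ identity × length plus
`Normal(0, score_noise_sd)`, one decoy hit per true hit into a different
cluster at identity_base − 5, and background spurious hits constructed
with SRV < 0.2. The decoys exist so that score noise has something to
overturn: at zero noise the true hit always outranks its decoy, giving
exact recovery; with growing noise the decoy wins increasingly often and
planted-pair recall degrades monotonically in expectation. Spurious hits
sit safely below the 0.3 SRV cutoff, so they exercise the filter without
ever becoming orthologs.

What the generator does not emulate: indels and alignment-length
variation, domain-level partial homology, gene order/synteny, in-paralogs
beyond identical copies, and realistic e-value distributions (e-values
are plausible constants per hit class). Passing the planted-truth tests
therefore shows the machinery is correct under the stated score model,
not that RBH orthology is biologically complete on real genomes.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems: 3–6 genomes,
tens of clusters, ≤ ~1000 hits, 100 randomized oracle-equivalence
instances and 20 seeds × 5 noise levels for the recall sweep — sizes at
which brute-force oracles are exact and the whole suite completes in
seconds. Floating-point scores are compared exactly where determinism is
claimed (byte-identical store files and TSVs) and with relative tolerance
~1e-6 where means are compared to oracles. Degenerate inputs: empty hit
streams produce a valid empty store; absent chunk keys yield empty
chunks; genomes without qualifying hits yield POCP 0 and AAI missing;
a genome with no active proteins is a POCP error.

## Known limitations

Order-dependent clustering on noisy data (inherent to the iterative
founder rule); no in-paralog handling beyond identical sequences; no
automatic SRV-cutoff estimation; single-writer store without concurrent
access; FASTA-only genomes lack coordinates, so the reference ortholog
track emits sentinel coordinates for them.
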