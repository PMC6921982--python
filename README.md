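# umidedup

Error-tolerant collapsing of reads tagged with Unique Molecular Identifiers
(UMIs).

UMIs are short random tags ligated to DNA molecules before PCR, so reads
that share a tag (and an alignment coordinate) are amplification duplicates
of one original molecule. Sequencing and PCR substitution errors scatter
each true UMI into a cloud of near-identical sequences, so naive
exact-sequence collapsing overcounts molecules. `umidedup` groups UMIs that
differ by at most *k* substitutions using the standard network-based
algorithms and keeps one consensus read per group — and does so without the
O(N²) pairwise distance matrix that makes large positions intractable.

## The model

Let *G* = (*V*, *E*) be the graph whose vertices are the *N* unique UMIs of
length *M*, with frequencies *f*(*v*), and an edge (*u*, *v*) whenever the
Hamming distance *d*(*u*, *v*) ≤ *k*. Three grouping algorithms operate on
*G*:

* **cluster** — connected components; transitive chains can "bridge" UMIs
  more than *k* apart;
* **adjacency** — visit UMIs by decreasing frequency; each seed claims its
  surviving direct neighbors;
* **directional** (default) — like adjacency but recursive, admitting a
  neighbor *v* of *u* only when *f*(*v*) ≤ ε(*f*(*u*) + 1) with ε = 0.5,
  i.e. the classic rule 2 *f*(*v*) − 1 ≤ *f*(*u*).

Instead of materializing *G*, all three are written against a two-operation
interface over a dynamic index: `remove_near(u, k, F)` returns-and-deletes
every surviving UMI within *k* edits of *u* with frequency ≤ *F*, and
`contains(u)` tests survival. Eight interchangeable index backends
implement it:

| backend     | idea |
|-------------|------|
| `naive`     | linear scan, O(NM) per query (the correctness oracle) |
| `combo`     | enumerate all sequences within *k* edits, hash-probe each |
| `subseq`    | index all C(M, k) placeholder-masked subsequences |
| `trie`      | prefix tree walked with an edits-remaining budget |
| `ngram`     | inverted index over k+1 positional n-grams (pigeonhole filter) |
| `bktree`    | metric tree pruned by the triangle inequality |
| `fenwickbk` | Fenwick tree over frequency ranks, a BK-tree per node |
| `ngrambk`   | one BK-tree per n-gram bin (default; fastest in practice) |

Distances cost O(1) per 21 bases: each nucleotide is a 3-bit code chosen so
the four codes are pairwise equidistant (A=110, T=011, C=101, G=000), which
makes the sequence-level Hamming distance `popcount(a XOR b) / 2`. `N` is
handled as a fifth letter through a separate position mask.

All backends produce bit-identical groupings; they differ only in speed.

## Worked example

Simulate a single-position dataset of 100 true molecules with UMI length
10, 20 one-substitution error copies per molecule, then deduplicate:

```
$ umidedup simulate -C 100 -M 10 -k 1 --seed 7 -o umis.tsv --sam reads.sam
unique_umis     1680
total_reads     14875

$ umidedup dedup-bam reads.sam -o dedup.sam
reads_in        14875
reads_out       100
positions       1
max_unique_umis 1680
dropped_no_umi  0
unmapped        0
```

The 100 true molecules were amplified (with errors) into 14,875 reads
carrying 1,680 distinct UMI sequences; the directional algorithm over the
default `ngrambk` backend collapses them back to exactly 100 consensus
reads. Index structure is inspectable too:

```
$ umidedup stats umis.tsv --backend ngram
n_umis  1680
n_bins  1576
avg_bin_size    2.1319796954314723
max_bin_size    19
```

The same operations are available as a library (`umidedup.simulate_dataset`,
`umidedup.build_index`, `umidedup.run_grouping`, `umidedup.dedup_bam`,
`umidedup.dedup_fastq`); FASTQ deduplication treats the whole fixed-length
read as the UMI, and SAM/BAM deduplication expects the UMI after the last
`_` of the read name, processing each (reference, strand, coordinate)
independently.

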