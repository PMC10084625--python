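# markerclust

Post-processing of marker-gene read alignments for detecting and quantifying
eukaryotes in shotgun metagenomes. Instead of relying on mapping quality to
pick a single best alignment per read, the pipeline keeps *all* alignments and
exploits the structure of shared alignments:

1. drop alignments shorter than 60 nt;
2. Markov-cluster (MCL) a graph of markers weighted by counts of shared read
   alignments;
3. average alignment identity per marker and per marker cluster;
4. reject taxa for which ≥ 50% of aligned markers fall below their cluster's
   identity average ("inferior" markers);
5. Markov-cluster surviving taxa on counts of multiply aligned reads;
6. report unambiguous taxa (average identity ≥ 97%, ≥ 2 reads on ≥ 2 markers),
   discarding their ambiguous cluster-mates;
7. report remaining clusters pooling ≥ 4 markers and ≥ 8 reads as one
   strong-ambiguous hit, labelled with the joined member names behind a `?`.

Detected taxa are quantified as copies per million (CPM): reads per kilobase
of evidence markers divided by sequencing depth in millions. All thresholds
are overridable.

The package also ships the surrounding evaluation toolkit: a wgsim-style
truth-labelled read simulator with mutation-rate sweeps, a scenario-driven
fixture generator (FASTA + taxonomy + truth table + SAM, fully synthetic, no
downloads), precision/recall scoring of mappings against truth at species or
genus rank, MAPQ-filter sweeps, and a pairwise taxon "confusability" analysis
(8 emit/accept rates per pair, PCA embedding, greedy distance-based
subsampling).

## CLI

```sh
# make a synthetic bundle to play with
markerclust fixtures --scenario detection-floor --seed 1 --out-dir demo/

# run detection + quantification on a SAM of marker alignments
markerclust detect --sam demo/detection_floor.sam --out report.tsv

# thresholds are flags: e.g. stricter identity, relaxed ambiguity floor
markerclust detect --sam aln.sam --out report.tsv \
    --min-identity 0.99 --ambiguous-min-reads 4 --total-reads 12000000

# simulate truth-labelled reads from a marker FASTA
markerclust simulate --fasta ref.fasta --coverage 0.1 --seed 42 \
    --out-fastq reads.fastq --out-truth truth.tsv

# score alignments against truth, sweeping a MAPQ filter
markerclust benchmark --sam aln.sam --truth truth.tsv --taxonomy taxa.tsv \
    --min-mapq 0 --min-mapq 30 --out metrics.tsv

# pairwise confusability from a read-flow table
markerclust confusability --flow-table flows.tsv --seed-pair "taxA|taxB" \
    --distance 0.005 --out-embedding embedding.tsv --out-subsample kept.txt
```

Reference sequence names are expected to encode the taxon and marker as
`taxon|marker` (first-delimiter split; configurable via `--delimiter` or a
regex pattern in the API).

## Layout

- `io_model` — SAM/BAM ingestion into a deduplicated alignment table
  (identity from NM tags, mate-tagged read ids, marker/taxon name parsing)
- `mcl_core` — Markov clustering of weighted undirected graphs
- `detect` — the seven-stage decision procedure
- `quantify` — CPM computation and TSV report writing
- `simulate` — read sampling, mutation sweeps, scenario fixtures
- `benchmark` — precision/recall scoring, MAPQ filtering, pair outcomes
- `confusability` — emit/accept rates, PCA, greedy subsampling
- `cli` — the `markerclust` command
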