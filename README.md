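# paleodam

A post-mapping, post-LCA authentication toolkit for ancient metagenomics.

Given a read-name-sorted BAM (with CIGAR, MD, AS and NM information) and a
matching LCA assignment text file (one read per line, taxonomic path from the
assigned node up to the root, in the same read order as the BAM), paleodam:

* **shrinks** the pair down to phylogenetically informative content — reads
  assigned at or below a rank threshold ("family" by default) with enough
  aggregated support (5 reads by default), keeping only alignments with
  similarity ≥ 0.9 (matches divided by full read length), with optional
  taxid exclusion lists, DUST-score ceilings, and PMD-score BAM annotation;
* **computes** per-taxonomic-node authentication statistics in one streaming
  pass: total/unaggregated reads, k-mer duplicity (total k-mers over a
  HyperLogLog unique-k-mer estimate, k=29, canonical k-mers, ≤1% error),
  mean DUST complexity (0–100, Prinseq-style scaling), 5'/3' terminal
  deamination frequencies (C→T, and G→A for double-stranded chemistry),
  mean read length, ANI, read/reference GC — under one of three
  alignment-weighting modes (best-alignment, per-read average, per-alignment);
* **post-processes**: multi-sample abundance matrices with read-weighted
  means (`combine`), per-taxon BAM extraction with best-alignment and
  top-reference options (`extract`), multi-sample damage-coloured Krona XML
  for `ktImportXML` (`krona`), deamination plots (`plotdamage`) and read
  length / mismatch histograms (`plotbaminfo`);
* **simulates** fully synthetic fixtures (toy taxonomy, references, damaged
  reads, matched BAM/LCA pairs) so every stage is testable offline.

Everything streams: both files are read in lock step without ever holding a
full BAM in memory, and reference context is rebuilt from query + CIGAR + MD,
so no reference FASTA is needed.

## Command line

```sh
# 1. shrink each sample (required before compute)
paleodam shrink --in-bam sample.bam --in-lca sample.lca \
    --out-bam sample.small.bam --out-lca sample.small.lca \
    --upto family --mincount 5 --minsim 0.9

# 2. compute per-node statistics (library chemistry is mandatory: ds or ss)
paleodam compute --in-bam sample.small.bam --in-lca sample.small.lca \
    --out-tsv sample.tsv --out-subs sample.subs --stranded ds --mode 1

# 3. downstream
paleodam combine --in-tsvs s1=a.tsv s2=b.tsv --out-tsv all.tsv
paleodam krona --in-tsvs s1=a.tsv s2=b.tsv --out-xml all.xml   # -> ktImportXML
paleodam plotdamage --in-subs s1=a.subs --taxid 9604 --stranded ds --out dmg.svg
paleodam plotbaminfo --in-bams s1=a.small.bam --out info.svg
paleodam extract --in-bam a.small.bam --in-lca a.small.lca \
    --taxids 9605 --out-bam homo.bam --best-only

# synthetic test data
paleodam simulate --out-bam toy.bam --out-lca toy.lca --seed 1 --damage 0.3
```

Every run writes a JSON manifest (`<output>.manifest.json`) with the resolved
parameters and seed. `compute` refuses LCA files that were not produced by
`shrink` unless `--force` is given. Boundary conventions are documented in
the module docstrings; notably the similarity threshold is inclusive (an
alignment at exactly 0.9 is kept) and the `--mincount` support filter uses
aggregated counts (a genus inherits support from its species).

## Tests

```sh
python -m pytest tests/
```

The suite is self-contained: all BAM/LCA inputs are generated at test time
by `paleodam.simulate`, and derived values are checked against independent
brute-force oracles (exact k-mer sets, triplet counters, path-membership
recounts, generator-truth reference segments).

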