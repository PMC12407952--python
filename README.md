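# sbtax

Taxonomy-aware Sequence Bloom Trees for indexing, profiling and
incrementally updating collections of microbial genomes.

## The problem

Metagenomic assembly recovers enormous numbers of genomes — many from
lineages with no named relatives. Placing a new genome (or
metagenome-assembled genome, MAG) into a taxonomy, and deciding when it
represents a *new* taxon, is usually done with fixed identity thresholds
(e.g. 95% ANI for species) that do not transfer across ranks or kingdoms,
and with monolithic k-mer indexes that must be rebuilt from scratch for
every database release.

`sbtax` takes a different route, aimed at people who curate genome
collections and need to characterize incoming genomes against them:

- Reference genomes are organized into a **seven-rank forest** (kingdom →
  species) in which every taxon owns a **Sequence Bloom Tree** (SBT): a
  tree of Bloom filters over canonical k-mers whose internal nodes are
  unions of their children. Species trees hold genome filters as leaves;
  genus trees use species roots as leaves, up to a single kingdom root
  holding every k-mer in the database.
- Similarity is alignment-free. For k-mer sets A and B the Jaccard index
  `J = |A∩B| / |A∪B|` is mapped to an average nucleotide identity estimate
  with the Mash transform `ANI = (1 + (1/k)·ln(2J/(1+J))) · 100`.
- Instead of one fixed threshold, every cluster carries dynamic
  **boundaries** — the min/max pairwise ANI among its genomes — and a
  query belongs to its closest species when its ANI to the species
  **centroid** reaches the boundary minimum.
- Genomes outside every boundary seed **new, unknown taxa** (`MSBT<n>`
  labels) via average-linkage clustering at boundaries inferred from
  sibling clusters; later reference genomes landing in such clusters name
  them by majority vote.
- Because the index decomposes along the taxonomy, an update **rebuilds
  only the affected root-to-species branch**; all other filters stay
  byte-identical.

A synthetic-genome generator with a planted 7-rank taxonomy makes the
whole pipeline testable end-to-end without downloading anything.

## Worked example

Simulate a small collection (9 species × 5 strains of 20 kb), index it,
and profile one genome:

```sh
sbtax simulate --out genomes --seed 42 --genome-length 20000 --strains 5
# wrote 45 genomes to genomes
sbtax index --genomes genomes --taxonomy genomes/taxonomy.tsv --out db -k 15
# indexed 45 genomes into 9 species
sbtax profile --db db --out profiles.tsv genomes/S5_03.fasta
# profiled 1 genomes -> profiles.tsv
```

`profiles.tsv` holds one row per rank:

```text
query_id  rank     closest_label  matched_kmers  matched_fraction  centroid_ani  within_boundaries  closest_strain  status
S5_03     kingdom  K1             19981          1.000000          82.338721     true               S5_03           assigned
...
S5_03     genus    G2             19981          1.000000          82.501842     true               S5_03           assigned
S5_03     species  S5             19981          1.000000          98.178345     true               S5_03           assigned
```

The query matches 100% of its 19,981 k-mers down the K1→…→G2→S5 branch; its
ANI to the S5 centroid (98.18) is inside the S5 boundaries, so it is
`assigned`, and the closest strain is (correctly) itself. `sbtax
boundaries --db db --out bounds.tsv` shows why: every species' boundary
minimum sits near 97.8–98.0 ANI (strains were simulated at substitution
rate 0.01, i.e. sibling ANI ≈ 98), while genus-level boundaries stretch
down to ≈81.

Updating the database with new genomes, naming unknown clusters with new
references, reclassifying a reference set at the 95%-ANI species
convention, and exporting an NCBI-style taxonomy dump for external k-mer
classifiers, are available as `sbtax update`, `sbtax refine` and `sbtax
export`; every command is a thin wrapper over library functions
(`sbtax.apply_update`, `sbtax.refine_references`,
`sbtax.export_classifier_inputs`, …).

## Layout

```
src/sbtax/
  taxonomy.py    lineages, genome/sample metadata records, quality tiers
  kmers.py       canonical k-mer extraction, distinct counts, filter sizing
  bloom.py       Bloom filters (add/lookup/union/density, serialization)
  similarity.py  Jaccard, Mash-ANI, pairwise matrices, average linkage, centroids
  sbt.py         SBT build / pruned query / union audit / serialization
  database.py    the 7-rank cluster forest, build, save/load
  boundaries.py  dynamic boundaries: compute, infer, audit
  profile.py     top-down profiling of query genomes
  update.py      dereplication, assignment, new taxa, voting, rebuilds, refine
  simulate.py    synthetic collections with planted taxonomy
  export.py      nodes.dmp/names.dmp + library export for k-mer classifiers
  cli.py         `sbtax` command-line interface
docs/methods.md  model, parameters, design choices, limitations
```
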