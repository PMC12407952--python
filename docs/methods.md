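# Methods

## Overview

`sbtax` organizes microbial genomes into a seven-rank taxonomic forest
(kingdom, phylum, class, order, family, genus, species) in which every
taxon owns a Sequence Bloom Tree (SBT) over the canonical k-mer content of
its genomes. Species trees have genome filters as leaves; a genus tree
uses its species' root filters as leaves, and so on up to a single kingdom
tree whose root covers every k-mer in the database. Decomposing one big
SBT along the taxonomy is what makes the index incrementally updatable: a
new genome touches exactly one root-to-species branch, which is rebuilt
locally while every other branch stays bit-identical.

## Signatures and filters

A genome is reduced to its set of canonical k-mers (the lexicographic
minimum of each window and its reverse complement; windows containing
non-ACGT characters are skipped). Canonicalization makes signatures
strand-invariant and halves filter load; the choice is recorded in the
database manifest so indexes are self-describing. Signatures are stored
exactly (sorted 64-bit integers, 2 bits per base), both because exact
Jaccard is cheap at this scale and because exact sets are required to
re-populate a child's k-mer content into the larger filters of higher
ranks, whose bit lengths differ.

Bloom filters use a single seeded splitmix64-style hash by default
(configurable). With one hash, the bitwise OR of two filters is exactly
the filter of the union of their input sets, which keeps SBT node
semantics exact. Filters have no false negatives; the false-positive
probability of a lookup at bit density `d` with `h` hashes is approximately
`d^h`.

### Filter sizing

Every cluster's filter length is planned from data: a species filter is
sized to the number of distinct k-mers across its genomes (optionally
discarding k-mers seen in fewer than `min_occurrence` genomes; the default
keeps singletons, appropriate for small viral genomes), a genus filter to
the distinct count over its species' union, and so on. Each raw estimate
is inflated by `1 + inflation` (default `inflation = 1.0`, i.e. 100%
headroom) and rounded up to a multiple of 64 bits. The headroom is what
lets the database absorb updates without filters saturating; rebuilds that
would push any node past the saturation ceiling (default density 0.95)
abort with an explicit error naming the node, and the remedy is a rebuild
with larger inflation.

## ANI from k-mer content

Similarity between genomes is the Jaccard index of their canonical k-mer
sets, J = |A∩B| / |A∪B|, converted to an average nucleotide identity
estimate by the Mash transform

    ANI = (1 + (1/k) · ln(2J / (1+J))) · 100 ,

clamped to [0, 100] (J = 0 would otherwise be −∞; the unclamped value is
available for diagnostics). The transform needs the Jaccard *similarity*:
at identity J = 1 the logarithm vanishes and ANI = 100, whereas plugging
in the complementary distance would diverge. Filters can stand in for
exact sets (popcount of AND over popcount of OR) at some accuracy cost;
the library computes pairwise matrices from exact signatures.

## Clusters, boundaries, centroids

Clustering is unweighted average-linkage agglomeration on the distance
100 − ANI, implemented directly (Lance–Williams update) so that ties merge
the lowest-index pair first and runs are bit-reproducible; scipy's
implementation serves as an independent cross-check in the test suite. A
dendrogram cut at threshold `t` keeps exactly the merges with height
≤ 100 − t.

Instead of fixed rank thresholds, each cluster carries dynamic
**boundaries**: the minimum and maximum pairwise ANI among the genomes
under it. Boundaries are only computed for clusters with at least three
genomes; smaller clusters borrow the mean boundaries of the computed
(non-inferred) siblings under the same parent, falling back to the
rank-wide mean and finally to configurable rank defaults (species
(95, 100) — the common 95%-ANI species convention; then genus 85, family
75, order 70, class 65, phylum 60, kingdom 50 as minima). Inferred
boundaries are flagged and recomputed as clusters grow; members that a
recomputation strands outside the new boundaries are reported as a
re-clustering queue.

Membership against boundaries is one-sided: a query is *within* a
cluster's boundaries when its ANI to the cluster **centroid** (the member
maximizing summed ANI to all other members, ties to the smallest id) is at
least the boundary minimum. A query more similar than the maximum — for
example, identical to the centroid — is obviously a member; a two-sided
test would reject it.

## Profiling

A query genome descends the forest top-down. At each rank the query's
k-mers are counted against every candidate cluster root; the best count c*
is found, and every candidate within 25% of it (count ≥ 0.75·c*) is
retained, a beam that guards against horizontal gene transfer dragging the
best raw count away from the true lineage. Only retained subtrees are
descended. At the species rank the retained candidates are re-scored by
ANI to their centroids, the verdict is taken against the winner's
boundaries, and the best-matching member genome is reported as the closest
strain.

A query whose kingdom-level match, **after false-positive correction**, is
below a configurable floor (default 1% of its k-mers) is `unassigned`. The
correction matters: a root filter at density d reports ≈ d·|Q| spurious
hits even for a query sharing nothing with the database, so the raw count
is first adjusted by (c − |Q|·d)/(1 − d). Queries that match the kingdom
but fail every species boundary are `partial` and carry the *deepest* rank
whose boundaries they satisfied. The deepest-first rule is deliberate: a
broad cluster's centroid can sit in a distant subtree (the kingdom
centroid lies inside some particular genus), so a shallow verdict may fail
for a genome whose genus-level verdict is comfortably positive, and must
not mask it.

## Incremental update

A batch flows through:

1. **Quality gate** (optional, off by default): genomes whose
   contamination exceeds 10% (`fail` tier) are excluded. Tiers follow the
   usual MIMAG-style cuts: high = completeness >90 and contamination ≤5;
   medium = completeness ≥50, contamination ≤10; low = completeness <50,
   contamination ≤10.
2. **Dereplication** at 99% ANI (default), greedy with database genomes
   kept first and batch genomes considered in input order; a dropped
   genome records its keeper. Greedy-first keeps references over MAG
   duplicates.
3. **Assignment**: genomes are profiled in deterministic order
   (descending signature size, then id). Each species hit immediately
   triggers an average-linkage clustering of the batch's pairwise ANI
   matrix cut at that species' boundary minimum, co-assigning the hit's
   whole block — this is what makes assignment largely order-insensitive.
4. **Second pass**: genomes that failed every boundary are re-profiled
   once after the first pass's attachments, because cluster growth can
   only widen computed boundaries (the minimum pairwise ANI is
   non-increasing under new members). With few genomes per cluster the
   boundary minimum sits close to the typical member distance, and
   marginal true members would otherwise be stranded into spurious
   singletons.
5. **New taxa**: still-unassigned genomes are grouped by identical partial
   lineage; at each group's first unfilled rank a boundary is inferred
   from the siblings under the same parent (same machinery as above), the
   group's ANI submatrix is cut at that boundary's minimum, and every
   block becomes a cluster labelled `MSBT<n>` from a monotonic counter
   that never reuses labels, recursing rank by rank down to species.
   Clusters built only from MAGs are unknown taxa by construction.
6. **Reference integration**: when newly added reference genomes land in
   an unknown cluster, it inherits their (majority) taxonomy and loses its
   unknown labels wherever no known ancestor conflicts; in a known
   cluster, the label is put to a majority vote over all member
   references' ingest-time taxonomies, ties broken lexicographically.
   Conflicts (an inherited species under a different known genus) are
   recorded and the existing parent lineage wins.
7. **Branch rebuild**: the species trees whose membership changed are
   rebuilt from genome filters, then their ancestors up to the kingdom;
   untouched branches are byte-identical before and after. Boundaries and
   centroids are recomputed and the boundary audit queue refreshed.

## Reference refinement

`refine_references` reclassifies a reference collection de novo:
average-linkage at a fixed cut (default 95% ANI), majority-vote label per
cluster, genomes whose original label differs from their cluster's label
reported as misclassified, labels that win no cluster reported as
vanished, and clusters sharing a winning label numbered `label|c1`,
`label|c2`, … in descending size order (ties by smallest member id).

## Synthetic data

The generator plants a known 7-rank taxonomy: a uniform-random root
sequence is propagated down the rank tree, each child an independent
per-site mutant of its parent at the branch's substitution rate (a
substituted site moves to one of the other three bases uniformly), leaves
are strains. Substitution-only by default, so closed forms stay available:
two siblings at branch rate r differ at an expected fraction
d = 2r(1−r) + (2/3)r² of sites, and the expected Mash-ANI of such a pair
is 100·(1 + ln(1−d)). The generator does not emulate repeats, GC skew,
horizontal transfer, incomplete assemblies or contamination, so passing
tests demonstrate the machinery's correctness under the stated divergence
model, not robustness to real MAG pathologies.

Default scenario: one kingdom/phylum/class/order/family, 3 genera, 3
species per genus, 10 strains per species (90 genomes), 50 kb genomes,
k = 15, species-branch rate 0.08, strain rate 0.01. These rates put
within-species ANI near 98 and between-species ANI near 86, so species are
unambiguous under the 95%-ANI convention. The genus-branch rate is 0.04:
it keeps between-genus ANI (≈73) far below within-genus boundaries (≈86)
while leaving cross-genus exact 15-mer sharing near 1.8%, above the 1%
kingdom floor — with much larger genus divergence, exact-k-mer overlap
vanishes entirely at k = 15 and genomes of a held-out genus would be
reported `unassigned` rather than founding new clusters, which is the
correct behaviour for truly alien sequences but not a useful default test
condition.

## Numerical and determinism choices

- All tie-breaks (pair merges, centroid, closest strain, label votes) are
  lexicographic or lowest-index; every pipeline is deterministic given its
  inputs, and re-running a build on identical inputs reproduces the
  database byte for byte.
- Bit-vector serialization is little-endian, LSB-first within byte, behind
  a magic/version header; loading rejects bad magic and unknown versions
  explicitly.
- Floats in on-disk tables are written at 17 significant digits so
  save→load is exact.
- ANI of two empty k-mer sets is defined as 1 (identical emptiness) with a
  warning.
- Problem sizes in the test-suite and acceptance script (mini scenario at
  12 kb / 5 strains; default scenario at 50 kb / 10 strains; 10⁵-element
  filter trials) were chosen so the full pipeline exercises every code
  path in a couple of minutes on one core.

## Known limitations

- Exact distinct-k-mer counting replaces streaming cardinality estimation;
  appropriate at this scale, not for hundreds of thousands of genomes.
- Plain union-filter SBT nodes are storage-redundant compared to
  determined/how split filters; that redundancy is the price of local,
  incremental updates.
- Assignment runs one pass plus one retry rather than iterating to a fixed
  point; pathological batches could remain order-sensitive.
- Only reference genomes vote in majority labelling; MAG-derived labels
  never do.
- AAI, read-level profiling, and alignment-based ANI are out of scope; the
  classifier exporter emits taxonomy/library inputs but does not build or
  run an external classifier.
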