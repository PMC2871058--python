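# Methods

`geneorder` analyses the conservation of adjacent gene pairs across
eukaryotic genomes. This note records the underlying model, the parameter
choices, the synthetic-data model used to exercise the pipeline, and the
numerical decisions a maintainer would need to know.

## Gene model and adjacency

A gene is a stranded coding interval: the 1-based inclusive coordinates of
the leftmost and rightmost CDS bases on one chromosome of one species.
Annotation sets usually contain several splice isoforms per locus; before
any adjacency analysis, same-strand coding intervals that overlap by at
least 1 bp (transitively closed into components) are collapsed to the
single record encoding the longest protein. Ties are broken by the
lexicographically smallest gene id so the result is deterministic.
Opposite-strand overlaps are biological (e.g. nested antisense genes) and
untouched. A consequence of the transitive rule: two same-strand genes from
genuinely distinct loci whose coding spans overlap are also merged; the
inputs we target do not distinguish that case from splice variants.

After dedup, the genes of each chromosome are ordered by start coordinate
and each consecutive pair is classified by relative transcription:

| left strand | right strand | class          |
|-------------|--------------|----------------|
| `-`         | `+`          | divergent (head-to-head) |
| `+`         | `-`          | convergent (tail-to-tail) |
| `+ +` or `- -` | same      | co-directional |

Under independent uniform strands, co-directional pairs occur at frequency
1/2 and each opposite-strand class at 1/4 — the baseline against which
biased genomes (e.g. polycistron-like fully co-oriented chromosomes) stand
out.

The intergenic distance of a pair is `right.start − left.end − 1` bp:
0 for abutting coding spans, negative when they overlap. Distances are
CDS-based throughout; UTRs are not modelled. Both the orientation class
and the distance are invariant under reversing a chromosome's coordinate
system (`x → L+1−x` with strands toggled), which the test suite checks as
a property.

## Homology grouping

Pairs are matched across species through per-gene homology labels under
two schemes: ortholog clusters (OrthoMCL `groups` format) and Pfam domain
architectures. An architecture is the ordered list of domains in a
protein; consecutive repeat runs are collapsed (`PPR PPR PPR → PPR`) so
that proteins differing only in repeat count share a label, while
non-adjacent recurrences (`A A B A → A~B~A`) are preserved because domain
order carries signal. A `collapse="global"` mode that keeps only the first
occurrence of each domain is available for comparison. Groups whose
members all come from one species carry no cross-species information and
are removed; their genes become unlabelled but still occupy genomic
positions and hence still define adjacency for their neighbours.

Architecture grouping is coarser than ortholog clustering (one
architecture often spans several clusters), so any pair matched under
clusters is also matched under architectures and architecture-based
species counts dominate cluster-based ones — a property test verifies
this on synthetic data where architectures are built by merging clusters.

## Canonical pair identity

The species-independent identity of a pair is (scheme, orientation class,
group labels). Divergent and convergent keys are unordered in the two
labels: the mirror image of a head-to-head pair is the same head-to-head
pair. Co-directional keys are ordered (upstream, downstream), where the
upstream gene is the one transcribed toward its partner; this order is
invariant under chromosome flipping and distinguishes `A→B→` from `B→A→`,
which differ transcriptionally. An `codirectional_ordered=False` switch
recovers fully unordered keys.

## Conservation score

A pair key found in a species set *S* is scored by the total branch length
of the minimal subtree of the species phylogeny spanning the leaves in
*S*: the union of all pairwise leaf-to-leaf paths, each edge counted once,
with no stem branch above the common ancestor. The implementation counts,
for each edge, the number of selected leaves below it and includes the
edge iff that count is strictly between 0 and |S|; this is O(tree size)
and exactly the union-of-paths definition. Excluding the stem makes the
score independent of where the tree is rooted (also under test). A
singleton set scores 0; scores are in the branch-length units of the input
tree. An independent brute-force oracle (explicit union of pairwise paths)
is kept in the synthetic-data module and compared against the fast scorer
over hundreds of random trees.

Aggregation: a species occurring several times for one key (tandem
duplications, histone-like arrays) counts once in the species set but
every occurrence contributes to the occurrence count and the mean
intergenic distance. Exported conserved-pair tables default to a
conservation floor of 0.3 to keep them at reporting size; the floor is a
parameter.

Summary curves: per orientation, counts of distinct conserved pairs in
0.01-wide conservation bins, with the cumulative count of pairs at least
as conserved as each bin's lower edge (non-increasing by construction).
The conservation-versus-distance relation is smoothed by lowess on
log10(mean intergenic distance) with fraction 0.3 and 3 robustifying
iterations; fewer than 10 points raises an error advising raw output,
and mean distances ≤ 0 are clamped to 1 bp before the log.

## Randomization null

Chance levels of cross-species sharing are estimated by shuffling, within
every species independently, the assignment of homology labels to gene
positions (uniform permutation; the per-species label multiset, including
unlabelled genes, is exactly preserved). Coordinates and strands are
untouched, so orientation-class frequencies are identical under the null.
For each of `n_replicates` (default 100) the fraction of distinct pair
keys appearing in ≥ 2 species is recorded; the mean fraction is the
chance-sharing probability, reported with a normal-approximation 95% CI,
alongside the null distribution of shared-key counts, a per-orientation
breakdown and an add-one empirical p-value for the observed count. A
small-case exact oracle (enumeration of all label permutations) validates
the Monte-Carlo estimate in the tests.

## GO similarity (GS²)

Annotations are closed under `is_a` ancestors, then the five uninformative
term names — cytosol, nucleolus, cytoplasm, protein binding, nucleus —
are removed by id (only the ids themselves; ancestors reached through
them stay). Names absent from an ontology are skipped with a warning. A
gene without annotation falls back to the combined closure of its
homology group. The two-gene GS² of closures C₁, C₂ is

    GS2 = ( |C₁∩C₂|/|C₁| + |C₁∩C₂|/|C₂| ) / 2 ,

symmetric, in [0,1], 1 iff the closures coincide, undefined (reported as
missing) when either closure is empty. 0.4 — the expected similarity of
random gene sets — is the threshold for calling a pair functionally
related. For a conserved pair the gene-level score is the mean over
occurrences with a defined score; a group-level mode scores the two group
closures once instead. Both denominators (pairs with defined scores, all
pairs) are reported in the fraction-related-by-conservation curve since
either convention is defensible.

## Bidirectional-promoter candidates

Candidates for a focus species are divergent conserved pairs with an
occurrence in that species at intergenic distance strictly below 1000 bp
(negative distances qualify — overlapping coding spans can still share a
promoter-bearing 5′ region) whose key occurs in at least 2 species.
When the pair occurs several times in the focus species the minimum
distance is used for the threshold and all occurrences are listed.
Ranking is by conservation, then GS², descending.

## Synthetic data model

The generator emulates the input the pipeline would receive from real
annotation sets, with planted ground truth:

- **Tree**: random ultrametric coalescent (pairwise joins, exponential
  waiting times) scaled to an expected root depth of 0.25 branch-length
  units, or a user Newick.
- **Genomes**: per species, gene lengths log-normal (median 1500 nt,
  σ = 0.5), intergenic gaps log-normal with archetype medians of 700 bp
  (fungi-like) or 30 kb (metazoa-like), σ = 1. Strands i.i.d. uniform, or
  a Markov "co-directional blocks" model. An optional divergent-excess
  mode converts a fraction of slots into 100–1000 bp head-to-head pairs,
  the mammalian bidirectional-promoter signature.
- **Labels**: a cluster inventory shared across species, independently
  permuted per species (so background adjacency is uncorrelated), each
  gene labelled with probability 0.8. Architectures merge every 2 cluster
  ids, making the architecture scheme strictly coarser.
- **Planted pairs**: orientation, species subset, intergenic-distance
  range and co-annotation probability per pair; each occupies a dedicated
  pair of labels at a fresh adjacent slot, with strands and gap overridden
  accordingly. The manifest records each plant with its expected
  conservation computed by the brute-force path-union oracle.
- **GO**: a layered random DAG of 500 terms in 6 layers (deeper layers
  wider, 1–2 parents per term); the first shallow terms carry the five
  blacklist names so the blacklist machinery is exercised. Genes receive
  1–3 random mid/deep terms with probability 0.5; adjacent background
  pairs share one deep term with probability 0.1; a planted pair is
  co-annotated — both genes get the pair's dedicated deep term — in each
  of its species independently with its configured probability. The DAG
  is deliberately deep so that two random genes' closures overlap only
  near the root and background GS² sits well below the 0.4 threshold,
  as with the real (much broader) ontology; a shallow DAG would push
  random-pair similarity to the threshold and drown the signal.

What the generator does not emulate: real splice-variant structure beyond
overlapping duplicates, gene families with internal synteny blocks longer
than pairs, UTRs, assembly artefacts, annotation error, and the very
heterogeneous per-source quirks of public genome releases. Passing tests
therefore demonstrate correctness of the pipeline's logic under a clean
model of its inputs, not robustness to dirty annotations.

Determinism: every stochastic choice flows from one `numpy` generator
seeded by the config; identical config and seed give byte-identical
output files.

## Problem sizes in the test and acceptance runs

The test suite runs the pipeline at 1–8 species with 60–250 genes per
species (thousands of genes in total), 200 random trees of up to 12
leaves for the score-oracle comparison, 100 shuffle replicates for the
null, and one 10,000-gene genome for the orientation-frequency check —
sizes at which every check completes in seconds while keeping the
binomial/Monte-Carlo error bands tight.

## Known limitations

- The dedup rule cannot distinguish same-strand overlapping distinct loci
  from splice variants (flagged above).
- The shuffle null permutes labels only; it preserves cluster-size spectra
  but not within-genome spatial autocorrelation of families.
- GS² here is the two-gene specialization; no information-content
  (Resnik/Lin) weighting, no evidence-code filtering.
- Chance-sharing probabilities depend strongly on the cluster-size
  spectrum of the dataset; synthetic values are comparable to real ones
  only in order of magnitude.
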