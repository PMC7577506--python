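# Methods

## The gene-neighborhood graph

The analysis unit is the ordered chain of orthogroup-labelled protein-coding
genes on each contig, sorted by start coordinate (1-based inclusive
throughout; ties broken by end coordinate, then gene id).  Genes without an
orthogroup assignment are omitted from the chains — their neighbors become
adjacent — and counted in the parse report, since the graph is defined over
orthogroup nodes only.  Nodes are orthogroups; for every consecutive pair
(u, v) in any chain a directed edge u→v is added, weighted by the number of
distinct genomes realizing the adjacency.  A genome contributing the same
adjacency on two contigs increments the weight once: the weight is a genome
count, not an occurrence count.  Edge direction follows post-coalignment
gene order; gene strand plays no role in the graph topology.

**Coalignment.**  Directed adjacencies are only comparable when all contigs
share an orientation.  Each non-reference contig is scored both ways —
count of ordered orthogroup adjacencies shared with the reference genome,
forward vs reversed — and flipped iff the reversed orientation strictly
wins; ties keep the input orientation, and the reference is never flipped.
This simple shared-adjacency objective is this package's own criterion for
"same orientation throughout the set"; it is exact for full reversals and
behaves like a majority vote for partial rearrangements.  The step is
optional (`coalign=False`) because its cost grows with the contig count on
large draft-genome sets.

**Paralogs.**  An orthogroup with ≥ 2 members in one genome has no single
chain position there.  `skip` (the default) removes all that genome's
copies while keeping the orthogroup for genomes carrying one copy — simple,
but those genes vanish from that genome's chains.  `orthologize` instead
partitions all copies of such an orthogroup by their (left-neighbor,
right-neighbor) orthogroup context and renames each context class
`<og>_p<i>`, with suffixes assigned in first-encounter order over
lexicographically sorted (genome, contig) keys so the relabelling is
deterministic.

## Complexity

Complexity is estimated per reference contig.  From every chain node,
`iterations` random walks (default 500) explore the graph: each step draws
a uniformly random out-neighbor — uniform over edges, deliberately ignoring
edge weight, so rare variants are found as readily as common ones — never
revisiting a node; a walk ends successfully the first time it draws a
reference-chain node and is abandoned when every out-neighbor of its
frontier is already on the path.  Unique successful paths of length ≥ 2 are
collected into a global pool keyed by node sequence.  Each pooled path
whose endpoints sit ≤ `window` chain positions apart (default 20) adds
`1/window` to every node strictly *between* the endpoints: the anchors
themselves are not bypassed by the path and receive nothing.  Two
consequences worth noting: direct chain steps (two consecutive reference
nodes) are legal paths but span no interior node, so they contribute
nothing; and all profile values are non-negative integer multiples of
`1/window`.  Walks that terminate on a reference node of a *different*
contig are discarded — chain distance is undefined across contigs.

Fixing the RNG seed makes the profile bit-reproducible.  The random walker
is validated against `enumerate_paths_exhaustive`, a depth-first
enumeration of every simple path whose interior stays off the chain; on
small sparse graphs 10⁴ walks per node recover the exhaustive set exactly,
and the accumulated profiles agree to machine precision.  The estimate
approaches the exhaustive value from below as `iterations` grows; 500 is
ample for graphs built from closely related genomes, where out-degrees are
small.

**Hotspots.**  The threshold is Q3 + k·IQR over the profile (quartiles by
linear interpolation, k = 1.5 by default — Tukey's outer-fence outlier
convention).  Genes strictly above it are hotspot genes; maximal
consecutive runs form regions reported with base-pair bounds from the
first gene's start to the last gene's end.  When the IQR is zero the
threshold degenerates to Q3 and k is irrelevant.  Raising k never adds
hotspot genes (the flagged *region count* may split, which is why counts
are reported per gene as well).

## Region subgraphs

A subgraph for a base-pair window [start, end] (capped at 100 kb to keep
renderings tractable) contains the reference nodes whose gene *start* lies
in the window, plus, from every other genome, maximal runs of non-region
nodes flanked by region nodes.  Runs of ≤ `depth` nodes (default 20) are
added whole; longer runs keep only their first and last `tails` nodes
(default 5), flagged `cropped_tail` and left dangling so renderers can mark
the truncation.  Runs that exit the window through a contig end are kept as
one-sided fragments, truncated where the genome rejoins the reference
backbone outside the region — from that point the sequence is ordinary
flanking context, not deviation.  Edges inherit graph weights; edges below
`minimal_edge_weight` are dropped and non-reference nodes thereby isolated
are pruned, so raising the filter is monotone (it never adds anything).
Exports: SIF with a weight sidecar TSV, and Cytoscape.js-style JSON with
`on_reference`/`cropped_tail` flags and product strings for display.

## The evolution simulator

The simulator is the validation harness: it generates genome sets whose
true per-locus variability is known, so the recovered complexity profile
can be scored against it.

A star phylogeny: every genome descends independently from a common
ancestor of `length` orthogroups (default 1,000).  The simulation applies
`n_steps` rearrangement events in total (default 3,000), each to a
uniformly chosen genome.  An event draws a type — insertion of novel
orthogroups, HGT from a shared foreign pool (default 100 orthogroups, so
transferred genes recur across genomes), deletion, or inversion — and a
target locus sampled proportionally to the predefined variability profile.
Segment lengths are geometric with mean 3, capped at 10 genes, for every
event type.  Weights are insertion 1, HGT 1, deletion 2, and inversion
0.01× the sum of the others (inversions are rare relative to other
rearrangements): the deletion weight equals insertion + HGT so the genome
length is balanced in expectation — zero drift plus random-walk noise
(per-genome s.d. ≈ 60 genes at 300 events).  Inserted and transferred genes inherit the ancestral-locus label
(hence the event probability) of their insertion site, keeping the profile
defined on the evolving genome.  The unevolved ancestor is included in the
set as genome `ancestor`, giving the complexity profile an exact
ancestor-coordinate frame.

Three profile shapes are provided, each normalized to sum 1 over loci:
sinusoidal `floor + (1+sin 2πi/p)/2`, rectangular (alternating high/low
blocks of width p/2) and sawtooth `floor + (i mod p)/p`.  Defaults: period
p = length/5 (five repeats across the chromosome, comparable to the
several-peak profiles real chromosomes show) and floor 0.1 (cold regions
rearrange at ~1/11 the hot-region rate rather than being frozen).

**Event budget matters.**  Recovery is only meaningful below saturation.
At ~3 events per locus and beyond, hot regions lose the ancestral anchor
genes deviating paths must return to within the window, and the measured
complexity there collapses — past that point the profile-complexity
correlation degrades and ultimately inverts.  The default budget (3,000
events across 50 genomes over 1,000 loci ≈ 0.06 events/locus/genome) sits
well inside the informative regime.

**Scoring.**  Both the predefined profile and the recovered complexity
vector are smoothed with the same sliding mean of width `window` before
correlating, because complexity is intrinsically window-averaged — a raw
per-gene correlation would understate agreement between a smooth target
and a piecewise-constant estimate.  Reported: squared Pearson correlation
and Spearman rho; constant vectors make both undefined and are reported as
0 with a `degenerate` flag.  With the defaults the pipeline recovers the
profiles at mean R² ≈ 0.74–0.77 and mean Spearman ≈ 0.89 over 30
replicates (sawtooth is the hardest shape — its discontinuous drop costs
Pearson correlation; sinusoidal and rectangular sit near R² 0.8).

**What the simulator does not emulate.**  Real genome sets share a
phylogeny (events are correlated between related strains), rearrangements
are not independent across loci (mobile elements target sequence motifs),
and orthogroup inference itself is noisy.  Passing recovery tests shows the
measure tracks true rearrangement frequency under idealized independent
evolution; it does not certify performance on real genome collections,
which must be evaluated on their own data.

## Numerical and design choices

- Quartiles by linear interpolation (`numpy.percentile` default); the
  hotspot comparison is strict (`>`), so a constant profile yields no
  hotspots.
- Walk neighbor choice: uniform over out-edges, not weight-proportional.
- Paths are deduplicated by exact node sequence across all start nodes.
- Multi-contig references: one profile per contig, computed against a
  termination set spanning all reference contigs; cross-contig paths are
  discarded.
- Region membership by gene start coordinate, inclusive on both ends.
- Profiles shorter than 2·window + 2 nodes trigger a warning; a window ≥
  the chain length is an error.
- Seeds: every stochastic component (walks, simulator) takes an explicit
  seed; replicate seeds are derived from a master seed via a seeded PRNG,
  kept below 2³¹.

## Known limitations

- The `skip` paralog policy removes duplicated genes per genome, which can
  shorten reference chains around multi-copy gene families; `orthologize`
  retains them at the cost of context-suffixed node identities.
- Complexity near chain ends is attenuated (fewer spanning paths fit the
  window); profiles on plasmid-sized contigs are mostly boundary.
- The coalignment objective considers whole-contig flips only; inverted
  segments within a contig are represented as deviating paths instead.
- Sampling with 500 iterations can miss very low-probability paths in
  extremely dense graphs; raise `iterations` (or use the exhaustive mode
  on small graphs) when exactness matters.
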