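# Methods

## Data model

The unit of analysis is a binary **presence/absence matrix** whose rows are
operational geographic units (OGUs) and whose columns are characters: species
presences, and — after BPA coding — hypothetical ancestors.  One
distinguished row, the *outgroup area*, is all zeros; it encodes the PAE
polarity assumption (absence is plesiomorphic) and roots every displayed
tree.  Matrices are validated on construction (binary cells, unique labels,
all-zero outgroup) and empty OGUs are dropped before analysis, so a gridded
dataset is analysed over its occupied quadrats only.

Gridding uses half-open cells `[west, east) x [south, north)` anchored at
integer multiples of the cell size from (0°E, 0°N).  Both the cell size
(default 5°) and the anchor are parameters; the half-open convention makes
boundary points deterministic.  Quadrat ids are assigned in row-major order
(south→north, west→east over occupied cells), so the labelling is invariant
to record order.  Province assignment goes through either a taxon→province
lookup table or GeoJSON polygons (shapely point-in-polygon; membership in
overlapping polygons is an error, points outside all polygons are reported,
never dropped silently).

## BPA coding and its inverse

Additive binary coding appends one column per internal node of a rooted
species cladogram; the value for area A is the inclusive OR over the node's
descendant species of their presences in A.  This is the original BPA
formulation: no area duplication and no assumption-1/2 recoding of
widespread taxa.  The coding demands that matrix characters equal tree
terminals exactly; species absent from the phylogeny must be subset away
explicitly by the caller (as was done for three species missing from the
case study's phylogenetic hypothesis).

The inverse operation recovers a cladogram from a coded matrix by bottom-up
agglomeration: repeatedly merge two current units whose area-vector OR
equals an unused ancestor column, with backtracking, memoisation of
fruitless states, and deduplication of choices that differ only in
interchangeable (identical-vector) units.  Because the coding lives at area
resolution, ancestors can share identical columns; such columns are flagged
as warnings and the returned topology is then one consistent resolution.
The shipped cladogram fixture was produced this way from the published
coding and is validated in the test suite by exact round-trip.

## Parsimony engine

Characters are unordered, equally weighted, binary, with no missing data.
State sets are packed as bitmasks (one bit per character per state), so a
Fitch merge is a few integer operations for the whole matrix at once.  At
nodes with more than two children the sequential pairwise Fitch fold is not
exact; the engine applies Hartigan's rule there (a state enters the
downpass set iff it occurs in a maximal number of child sets; the cost is
children minus that maximum), which is exact on hard polytomies and
coincides with Fitch at degree two.

**TBR scoring.**  Bisecting an edge leaves two subtrees whose Fitch lengths
are invariant to where they are later attached; the length of any
reconnection is `L1 + L2 + join(e1, e2)`, where the join cost counts
characters whose edge-view state sets (the merge of the two directional
downpass sets at the attachment edge) are disjoint.  Directional sets for
all edges of a component are computed in one down/up pass, so a full TBR
sweep over a tree costs O(edges²) joins of a few integer operations each.
The identity of this formula with direct re-scoring is property-tested.

**Search.**  Each replicate builds a Wagner tree under a random addition
sequence and descends by steepest TBR.  Every tree reaching the current
best length enters a pool keyed by its *collapsed* topology; each pool
member is swapped in turn and any equally parsimonious rearrangement with a
new collapsed topology joins the pool, until the pool is closed under TBR
("swap to completion").  A strictly better tree resets the pool.  Defaults
(100 replicates, 10,000 retained trees) follow common practice for matrices
of this size; at 21 areas the closure is reached within the first few
replicates and the result is independent of seed, which is why the
acceptance run reports identical values for any seed.  An optional
parsimony ratchet (reweight ~25% of characters by bit duplication, swap,
restore, swap) is available as an accelerator but off by default.

**Collapse rule.**  Counts of distinct optimal trees use the
minimum-length-zero rule: an internal branch is collapsed iff some
most-parsimonious reconstruction places no change on it.  Because per-
character optima combine freely, this is equivalent to: for every
character, the minimum cost with equal end states equals the optimum.  The
implementation computes this by an exact per-character dynamic program over
both edge orientations.  A tempting shortcut — testing whether the two
directional Fitch sets intersect — is *not* exact (brute-force enumeration
exhibits collapsible edges it misses) and is deliberately not used; getting
this wrong inflates the count of "distinct" optimal trees.

**Branch and bound.**  An exact enumerator (sequential taxon insertion with
length-monotone pruning) returns provably all optimal trees for up to 14
areas and serves as the internal oracle for the heuristic; a no-pruning
variant enumerates every topology for up to 9 areas and in turn checks the
branch-and-bound.

**Tree statistics.**  `m` counts variable characters (each needs at least
one step on any tree; constant columns contribute nothing), `g` sums
`min(#1s, #0s)`, `s` is the observed length; `CI = m/s`, `RI = (g−s)/(g−m)`.
Values are exact fractions internally and rounded only for display, three
decimals, half-up (0.6052… → 0.605, 0.6428… → 0.643).  A zero-length matrix
reports CI 1.0 with a flag.

## Consensus and character optimisation

The majority-rule consensus retains exactly the ingroup clades occurring in
strictly more than the cutoff fraction (default 50%) of the optimal trees,
rooted on the outgroup.  Strict inequality is deliberate: with an even
number of optimal trees, exactly-half clades would make the consensus
depend on tie-breaking; under the strict rule the result is well defined.
A clade present in half of the trees is therefore dropped.  Node
frequencies are recorded per retained clade.  When counting consensus
nodes, the root polytomy counts once and the outgroup junction is not a
node; published figures that count it will read one node higher.

Characters are optimised on the consensus topology itself, polytomies
included, by an exact in/out dynamic program per character.  For each
branch the joint cost of every (parent state, child state) pair is compared
with the global optimum: a branch is an *unambiguous gain* for a character
iff (0,1) is the only optimal pair; likewise for losses; any branch where a
change is merely co-optimal is flagged ambiguous rather than resolved by
ACCTRAN/DELTRAN-style preference.  Because the consensus may be less
resolved than the optimal trees, its total step count can exceed the
optimal length; the package reports it separately and never substitutes it
for the search length.

## Areas of endemism

A candidate area set is every single OGU and, when a consensus is supplied,
every consensus clade's leaf set.  A candidate qualifies iff at least
`threshold` (default 2, the conventional criterion) characters have a
presence set *exactly equal* to the candidate — taxa found everywhere
inside and nowhere outside.  Raising the threshold can only remove entries;
the report is invariant to row/column permutations of the matrix.

## Synthetic data generator

The generator emulates the two processes the analyses are meant to
distinguish.  A rooted binary *area history* splits an ancestral region
into nested, non-overlapping rectangles (default: four 5°×5° rectangles in
a 2×2 block, aligned to the default grid so gridding reproduces the
terminal areas exactly).  Lineages start in the root region; at each split
a resident lineage speciates into the two daughters with probability
`p_vicariant` (default 0.8), otherwise it persists as a single widespread
species across the whole splitting region and is not subdivided further.
A species' range is therefore always the terminal-area set of one history
node, which is precisely what gives presence data their hierarchical
signal: a lineage that fails to respond to a barrier becomes a widespread
taxon spanning a clade of areas.  (The alternative — confining a
non-speciating lineage to one side — would leave every species in a single
area and make the history unrecoverable from presences by construction.)
After the history completes, each species expands with probability
`p_dispersal` (default 0.1) into one uniformly chosen terminal area
adjacent to its range (shared edge, not corner); this single-step range
expansion is the sole source of homoplasy.  Finally
`n_points_per_species` (default 30) occurrence points are drawn uniformly
within each species' rectangles, area-weighted.  Everything is driven by
one seed and fully reproducible.

Two corner cases calibrate expectations.  With `p_vicariant = 1` and no
dispersal every species is endemic to one terminal area; the species-level
matrix is then an identity matrix and carries no grouping information for
*any* method — recovery of the history in this regime runs through BPA
coding, whose ancestor characters are exactly the history's clades, and the
test suite verifies Robinson–Foulds distance 0 over 20 seeds this way.
With dispersal switched on, species ranges stop being clades and the
ensemble consistency index drops below 1, which the suite verifies as a
Monte-Carlo average.

What the generator does not emulate: georeferencing error, spatially biased
sampling effort, non-rectangular or disjunct ranges, extinction, and
within-area speciation.  Passing the recovery tests therefore shows the
pipeline is sound on clean vicariant signal with bounded dispersal noise,
not that real occurrence compilations meet those assumptions.

## Problem sizes and determinism

The bundled case study runs at its natural size (21 areas × 23 and 39
characters; seconds per search).  Property tests use 4–9 areas against
brute-force oracles (exhaustive state assignments, exhaustive topology
enumeration), 50 random 8×10 matrices for heuristic-vs-exact equivalence,
100 random cladograms (up to 20 terminals) for coding round-trips, and 20
seeds for the recovery experiment — sizes chosen so each oracle remains
exhaustive.  All randomness flows from explicit seeds; a fixed seed
reproduces tree sets, summaries and simulator output bit-for-bit.

## Known limitations

* Binary characters only; no missing data, ordered states or weights
  (the matrices this package targets contain none).
* Secondary BPA (area duplication) and assumption-1/2 coding variants are
  out of scope.
* Branch-and-bound is limited to 14 areas by design; beyond that the
  closed TBR search is the tool, and its completeness, while verified
  exhaustively at oracle sizes and stable across seeds at case-study size,
  is not a proof.
* The taxon cladogram recovered from an area-level coding is unique only up
  to ancestors with identical columns; such ambiguity is flagged, not
  resolved.
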