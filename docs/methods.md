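# Methods

## Matrices and symbols

Alignments are taxa × column matrices over `{A,C,G,T}`, the partial IUPAC
ambiguity codes, `N`, gap `-` and missing `?`.  Gap and missing are kept
distinct at I/O level; parsimony treats both (and `N`) as the full state
set, and partial ambiguities as partial state sets (`R = {A,G}`, …).  A gap
is never a fifth state.  Taxon labels are normalized by mapping internal
whitespace to underscores; comparison stays case-sensitive.  Partition maps
use 0-based half-open column intervals that tile the supermatrix.

## Operational outgroup

The statement encoding needs a polarity reference.  It is built as the
majority-rule consensus of a designated outgroup taxon set: per column,
frequencies are computed over *applicable* symbols — the four nucleotides
only; gap, `?` and `N` never enter the denominator, and partial ambiguities
are excluded by default (`ambiguity="fractional"` instead splits an
ambiguity's unit weight equally among its nucleotides).  A column
contributes a consensus state only when its modal state is unique and
reaches the threshold (default 0.5); ties — even at the threshold — give
`?`, not an IUPAC code.  This is deliberately conservative: a `?` column is
simply skipped by the encoder, whereas a guessed state would mint polarized
statements from an undecided column.  Raising the threshold can therefore
only turn states into `?`, never the reverse (property-tested).  Outgroup
expressions written with internal nesting carry no computational weight;
the consensus is flat over the listed taxa.

## Statement encoding

For each column with outgroup state in `{A,C,G,T}`, each derived nucleotide
present in the ingroup yields one binary recoding: carriers score 1, and
the 0 set follows the configurable *zeros convention*:

* `absence` (default): every nucleotide-scored taxon lacking the derived
  state, including taxa with a different derived state — the reading of the
  encoding as a plain presence/absence (binary) representation;
* `plesiomorphic`: only taxa carrying the outgroup state.

Taxa with gap/`?`/`N`/partial ambiguity are unscored in every recoding.  A
recoding with *n₁* ones and *n₀* zeros expands to C(*n₁*,2)·*n₀* statements
*ij*|*k*; identical statements from different columns are merged with their
provenance retained, each occurrence keeping uniform weight 1.  Statements
are aggregated in a single pass; the expanded binary matrix is only ever
written on request (NEXUS `SYMBOLS="01" MISSING=?`, one column per
occurrence, including the all-zero operational outgroup row) and is never
needed in memory: lengths and ensemble statistics come from the aggregate.

## Parsimony

Column lengths use a unit-cost dynamic program over the four nucleotide
states (cost of each state at a node = sum over children of
min(child cost of same state, child minimum + 1)).  This is exact for
multifurcating trees and set-valued leaves, reduces to Fitch on binary
trees, and is vectorized across columns with site-pattern compression.  For
binary statement characters, ordered (Wagner) and unordered (Fitch)
parsimony coincide.

Statement matrices are scored directly by the ancestor rule: on the tree
rooted at the operational outgroup, *ij*|*k* costs 1 step when the most
recent common ancestor of {i, j} is a proper descendant of that of
{i, j, k} (equivalently, *k* lies outside the smallest cluster containing
*i* and *j*) and 2 steps otherwise, so L = N + V.  The equivalence of this
rule with summed Fitch lengths over the expanded binary columns is the
module's central invariant and is enforced on 200 random instances in the
acceptance suite.

Per-character statistics on DNA columns use the closed forms
m = (#observed nucleotide states − 1) and g = (#nucleotide-scored taxa) −
(largest state class); ambiguity codes count as missing for m and g (their
step contribution is still exact).  Ensemble CI = Σm/L and
RI = (Σg − L)/(Σg − Σm); RI is NaN when every character is uninformative.
For uniform statement matrices these reduce to CI = N/L, RI = (2N − L)/N,
computed from the aggregate and never from materialized columns.

### Search

`mp_search` uses random-addition starting trees (the operational outgroup,
when present, is always seeded into the starting triple so partial trees
stay scorable) followed by branch swapping: `nni`, `spr`, or the default
`tbr`, which is SPR plus re-hanging of pruned clades of ≤ 8 leaves by their
pendant edges (a bounded TBR reconnection; `full_tbr=True` lifts the
bound).  Equally optimal distinct topologies are pooled up to
`max_trees_per_replicate`, deduplicated by split/cluster sets, and reported
in canonical newick order; the whole search is deterministic under a fixed
seed.  `exact_search` enumerates all unrooted topologies (≤ 9 leaves) as
the oracle.  The swap-radius ordering nni ≥ spr ≥ tbr on a fixed seed is
property-tested.

### Jackknife

Each replicate deletes round(fraction · #characters) characters without
replacement — columns for DNA matrices, statement occurrences (sampled
multivariate-hypergeometrically from the multiplicities) for statement
matrices — re-searches, and records the splits of the replicate's strict
consensus; support is the percentage of replicates containing a split.  The
conventional deletion fraction 0.37 ≈ e⁻¹ is the default.

## Tree comparison

Robinson–Foulds distance is the symmetric difference of cluster sets
(rooted mode) or bipartition sets (unrooted).  When a call does not fix the
mode, rooted is used iff every input carries a root — the workflow's trees
are rooted by their operational outgroups.  Strict consensus keeps groups
present in all inputs; majority-rule keeps groups in strictly more than the
threshold fraction (groups at exactly the threshold are excluded).

**RF median.**  A split present in more than half the inputs lowers the
summed RF distance when included, one in fewer than half raises it, and one
in exactly half is neutral; majority splits are mutually compatible.  The
majority-rule consensus is therefore an exact RF median at any size — no
search needed.  Neutral 50% splits are then added greedily in deterministic
order while compatible, implementing the prefer-the-most-resolved
tie-break.  Exhaustive enumeration over all topologies (an independent
recursive generator in the tests) confirms the minima.

**RF supertree.**  Inputs on overlapping leaf sets (the overlap graph must
be connected) are combined into a tree on the leaf union minimizing the
summed RF between each input and the supertree restricted to that input's
leaves.  Restriction operates directly on group sets.  For small unions the
optimum is found exhaustively: every binary topology plus all contractions
of its internal edges, deduplicated by group set — multifurcating optima
are real; contracting only the best binary tree is not sufficient.  This
enumeration is feasible to 8 unrooted / 7 rooted union leaves (10395 binary
shapes × ≤ 32 contraction subsets); beyond, a heuristic builds a backbone
from the largest input, inserts missing leaves at the score-minimizing
position, and refines by greedy group deletion and addition of
input-supported compatible groups.  The reported score is exact for the
returned tree in either regime.

## Synthetic data

`SimConfig` defaults emulate the shape of a multi-locus plastid
supermatrix: tens of taxa, 10 loci of unequal length (400–1200 columns),
two basally attached outgroup taxa, 15% per-taxon locus dropout padded as
`?` (outgroup rows are exempt so polarity survives), and short gap runs
(rate 0.002/site, mean length 4).  Trees are pure-birth (Yule) with natural
waiting-time branch lengths — a higher birth rate yields shorter branches —
with outgroup stems at 0.5×/0.75× the ingroup depth.  Sequences evolve
under Jukes–Cantor with per-locus rates expressed as substitutions per site
across the total tree depth (defaults 0.05–0.15, spanning slow and fast
loci), so divergence is rate-controlled regardless of the Yule time scale.
The default rates put the simulated change density (conventional tree
length per column ≈ 0.6) at the level observed in real plastid
supermatrices of this size class.  All randomness flows from one seed
through named per-stage generators, so each stage is independently
reproducible.

What the generator does *not* emulate: realistic indel evolution (gaps are
injected noise, not evolved), rate heterogeneity across sites within a
locus, base-composition bias, and alignment error.  Passing recovery tests
therefore demonstrate statistical behaviour of the estimators under clean
model conditions, not robustness to real-data pathologies.

## Pipeline

The global stage subsets the supermatrix to a working taxon list (an
explicit user input — which taxa to retain is an analytical decision),
builds the consensus outgroup, encodes, and searches.  Local stages repeat
encode-and-search inside user-defined clades, each against its own
(typically sister-group) consensus outgroup; with several optimal trees,
both the strict consensus and the RF median are produced — the median is a
minimal-distance summary where the strict consensus generally is not.  The
minimal topologies (single optima or medians), stripped of their
operational outgroup leaves, are combined into one RF supertree.  A run
manifest records per-stage statement counts, lengths, violation counts,
RI, seeds and output hashes, sufficient to re-run bit-identically.

## Observed estimator behaviour

On simulated 20-taxon supermatrices the 3TA pipeline's recovery of the
generating topology is strongly length-dependent: near 0/5 at 1000 columns,
about 70% at 4000, and ≥ 90% from ~20000 columns (locus length 2000), with
every failure traceable to the statement-matrix optimum being strictly
shorter than the generating topology — an estimation property, not a
search failure.  Conventional parsimony on the same matrices shows a
comparable rate at 4000 columns and, at 20000, occasionally prefers a tree
one rearrangement away from the truth under the pull of the long outgroup
branches — a long-branch effect the 3TA's consensus outgroup avoids, since
its polarity reference is a profile rather than a terminal.  The test suite
asserts the behaviour actually observed at fixed seeds; problem sizes in
the suite (5–20 replicates, 4000–20000 columns) were chosen to keep the
checks deterministic and desk-scale.

## Numerical and design notes

* Leaf-cost "infinity" in the column DP is a large finite int32; it can
  never propagate past a node because child contributions are capped at
  (child minimum + 1).
* Tree identity/deduplication uses frozen split or cluster sets; reported
  tree lists are sorted by canonical newick for determinism.
* `exact_search` refuses > 9 leaves (135135 topologies at 9) and points to
  `mp_search`.
* Jackknife deletion counts use round(), so fraction → 0 degenerates to the
  full search in every replicate.
* The NEXUS dialect is minimal: DATA/TAXA/CHARACTERS/TREES with optional
  interleaving; SETS and ASSUMPTIONS blocks are ignored with a logged
  warning.
* Known limitations: no implied weighting, no bootstrap, no
  likelihood/Bayesian criteria, no fractional statement weighting, and the
  supertree heuristic above the exhaustive cutoffs guarantees only the
  exactness of its reported score, not global optimality.
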