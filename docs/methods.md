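# Methods

## Objective

For one character on one rooted binary tree, the package scores

    score = steps + extra_regions

*Steps* are transformations between distinct applicable states along
edges. A *region* (equivalently, a subcharacter) is a connected part of
the tree throughout which the character is applicable; every region beyond
the first counts one point, because a second independent origin of the
same dependent condition is homoplasy even when no transformation is
implied. Edges joining an applicable and an inapplicable vertex are free:
losing the principal structure loses its attributes with it, and charging
those losses again per dependent character would over-penalize loss. We
reserve *tree length* for the number of transformations and *tree score*
for the combined objective.

Matrix scores are sums of independent per-character scores (unit weights;
the search temporarily doubles some weights, nothing else).

## Assumptions about the data

1. Principal and dependent characters are separate columns; `-` marks
   cells where a character cannot logically be observed, `?` marks cells
   that were not observed. Both tokens are honored in NEXUS and TNT input
   even when a file declares only one of them.
2. The `-` distribution of a dependent column matches the absence
   distribution of its principal column. Nothing needs to declare *which*
   column is the principal one; the algorithm never uses that information.
3. Missing data expand to "any state, applicable or inapplicable"
   (`expand_missing(..., "all_states")`, the default applied by the
   scorer). The alternative policy `applicable_only` is available but not
   used implicitly.
4. Characters are unordered and unit-weighted. Ordered/additive multistate
   characters, step matrices and non-unit weights are out of scope.
5. Per-character alphabets come from the symbols observed in that column,
   so missing expansion ranges over the states the character actually
   exhibits.

## The four passes

Scoring needs three traversals, ancestral states a fourth. Every rule is
local to a node, its two children, and (in uppasses) its parent.

1. **First downpass** (post-order) builds preliminary state sets that
   track applicability. If both children carry applicable states and at
   most one carries the inapplicable state, the node takes the shared
   applicable states (their intersection, falling back to the union when
   they share none — the Fitch convention). If both children carry the
   inapplicable state and at most one carries applicable states, the node
   is the inapplicable singleton. Otherwise the node takes the union of
   everything.
2. **First uppass** (pre-order) resolves every vertex as applicable or
   inapplicable. A purely applicable preliminary set stands. A *mixed*
   set resolves with the resolved ancestor: applicable ancestor keeps the
   applicable part, inapplicable ancestor forces the inapplicable
   singleton. A vertex whose preliminary set is exactly the inapplicable
   singleton becomes applicable (with its children's applicable states)
   only when its ancestor is applicable *and* a child offers applicable
   states — two of its three neighbours then exhibit the character. The
   root has a phantom applicable ancestor, so mixed ambiguity at the root
   resolves toward presence: parallel losses are preferred over loss and
   regain. This preference is what makes the method locally rather than
   globally optimal.
   Ambiguous *tips* (sets holding both applicable states and the gap,
   i.e. expanded `?` cells) then resolve to match their parent's
   applicability.
3. **Second downpass** (post-order) is plain Fitch restricted to
   applicable vertices: shared child states are kept at no cost; disjoint
   applicable child sets unite and add one step. A boolean *tracker* per
   node records whether its subtree contains any applicable tip; whenever
   the two child trackers are both true at a vertex that cannot connect
   them through itself (an inapplicable vertex, or an applicable vertex
   with at most one applicable child), one region count is added. The
   tracker is never reset, so each junction of two region-bearing
   subtrees is counted exactly once, and `extra_regions` ends up as
   (number of regions − 1) for any labeling consistent with the passes.
4. **Second uppass** (pre-order) finalizes ancestral sets with the
   standard Fitch final-state rules applied to applicable states, with
   two modifications: a vertex whose ancestor is inapplicable is the root
   of its own region and keeps its working set, and ancestor states are
   added across an inapplicable child. This pass never changes the score.

**Threshold.** A character with fewer than three `-` singletons can never
force a second region, so such columns (and columns with no `-` at all)
are dispatched to ordinary Fitch with `-` treated as missing. This is
exact, not an approximation, and keeps the expensive path proportional to
the characters that need it.

### Where the published description is ambiguous

The prose description of the first uppass ("two or more adjacent nodes
applicable") can be read as flagging a vertex applicable whenever any two
neighbours carry applicable states, including through the root's phantom
ancestor. Implemented literally, that reading breaks the symmetry
property (identical score under every rooting): an ambiguous tip adjacent
to the root gets pulled into applicability on some rootings only. The
resolution implemented here (mixed sets follow the ancestor; inapplicable
singletons additionally require an applicable child; the phantom ancestor
acts only on mixed root sets) reproduces all published worked cases and
is exactly rooting-invariant — verified exhaustively over every edge of
hundreds of random instances in the test suite.

## Guarantees verified by the tests

- **Fitch equivalence**: without `-` tokens the total equals the textbook
  Fitch length (an independently coded recursive Fitch is the oracle).
- **Threshold**: with ≤ 2 inapplicable singletons the total equals the
  missing-treatment length.
- **Rooting invariance**: identical totals across rerooting on every
  edge.
- **Oracle bound and self-consistency**: on trees small enough to
  enumerate every labeling, the total never undercuts the exhaustive
  minimum of the same objective, and some single-state selection from the
  final sets achieves exactly the reported total. The exhaustive minimum
  may be strictly smaller: a global optimizer may connect regions through
  unobserved ancestors, which the local presence-over-absence resolution
  forbids. The oracle is therefore a lower bound, not an equivalence
  target.
- An invariant dependent character (one applicable state) split into
  separated regions still contributes score, so it informs a search.

## Baselines

Both traditional treatments run one shared Fitch engine and differ only
in token mapping — `missing`: `-` and `?` map to the full applicable set;
`extra_state`: `-` is a (k+1)-th state and `?` spans all k+1. This
guarantees the three methods differ only in their stated treatment of the
gap. The missing treatment is a relaxation, so its length never exceeds
the extra-state length.

## Search

The parsimony ratchet alternates hill climbing under perturbed weights (a
random 25 % of characters doubled — the published protocol does not state
its perturbation scheme; the fraction is configurable) with hill climbing
under original weights, always adopting the iteration's end tree so the
walk can traverse equal-score regions. Hill climbs use NNI neighborhoods
by default (SPR optional; TBR omitted) and walk score plateaus up to a
bounded island size (200 trees) looking for an improving exit — without
this, small matrices with broad plateaus trap the search in its first
basin. All distinct topologies attaining the best score are retained,
canonicalized as unrooted split sets, with a 10 000-tree cap and an
explicit overflow flag. Runs are bit-reproducible given a seed. On
matrices small enough to enumerate every topology, the ratchet's best
score matches complete enumeration for all three methods in the test
suite; no claim is made about equivalence with any other program's search
internals.

## Synthetic hierarchies

`simulate_hierarchy` evolves a principal binary character by a two-state
gain/loss chain (default rates 0.2/0.2 per unit branch) on a Yule tree
with unit branch lengths, and each dependent character by a symmetric
chain (default total rate 0.3, two states) along lineages where the
principal state is *present*; a regained structure draws its dependent
state uniformly afresh. Dependent cells are emitted as `-` exactly where
the principal tip state is absent; an optional uniform `missing_rate`
then replaces cells with `?`. Defaults (16 taxa, 3 dependents) give
matrices where roughly half the taxa bear the structure and characters
carry a few changes each — enough signal that the generating topology
scores no worse than random trees on average, which the tests check.

What the generator does **not** emulate: rate heterogeneity across
lineages or characters, correlated dependents, non-uniform missingness,
and polymorphic observations. A green test on synthetic data therefore
establishes the coding structure and the algorithm's combinatorial
behavior, not realism of morphological evolution.

## Numerical and representational conventions

- State sets are integer bit masks (≤ 32 applicable states plus one
  inapplicable bit); `mask == 0` is the pre-expansion missing marker and
  is rejected by the scorer.
- Polymorphism `(..)`, ambiguity `{..}` and TNT's `[..]` are treated
  identically as multi-state sets.
- Step and region costs are both exactly 1; no tie-breaking is ever
  needed because the pass rules are exhaustive and mutually exclusive
  (asserted over all child-set classes in the tests).
- Canonical tree identity is the set of nontrivial bipartitions of the
  unrooted topology, so differently rooted copies of one topology are
  tallied once.
- Scoring requires strictly binary trees; parsing accepts polytomies and
  `resolve_polytomies(tree, rng)` binarizes them explicitly — never
  silently.
- The brute-force oracle enumerates every single-state labeling (internal
  vertices range over applicable states plus the gap, tips over their
  expanded sets), refusing instances beyond `max_nodes` internal vertices
  or ~3 × 10⁶ labelings.

## Known limitations

- Local optimality: scores can exceed the global minimum of the
  objective on adversarial instances (by design; the exhaustive oracle
  quantifies this on small trees).
- Single-character optimization only; simultaneous multi-character
  resolution of nested hierarchies is out of scope.
- No Sankoff step matrices, character weights, ordered characters or
  branch lengths.
- The ratchet is a heuristic: on large matrices completeness of the
  optimal set is not guaranteed, and the collection cap may truncate huge
  tree islands (flagged via `overflow`).
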