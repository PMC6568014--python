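# inappfitch

Parsimony scoring, ancestral-state reconstruction and tree search for
discrete morphological matrices that contain **inapplicable** character
states.

## The problem

Morphological characters are frequently hierarchical: "tail colour" only
means something in taxa that have a tail. Reductive coding writes such
cells with the gap token `-` ("inapplicable"), distinct from `?`
("missing"). Standard parsimony programs must then either treat `-` as
missing data — which lets trees reconstruct logically impossible events
such as a change of tail colour in a tailless ancestor and thereby
under-counts homoplasy — or as an extra state, which over-penalizes every
loss of the principal structure once per dependent character.

`inappfitch` implements a single-character, Fitch-style algorithm that is
aware of the inapplicable state. A character's contribution to the tree
score is

```
score = steps + extra_regions
```

where *steps* counts ordinary state transformations within regions of the
tree where the character applies, and *extra_regions* counts additional
connected regions of applicability beyond the first — each independent
origin of the same dependent condition is homoplasy and is charged one
point. The algorithm uses up to three tree traversals to score a tree
(first downpass, first uppass with tip resolution, second downpass with a
per-node region *tracker*) and a fourth to finalize ancestral state sets.
Ambiguous applicable/inapplicable vertices resolve toward presence
(parallel losses are preferred over loss and regain), which makes the
method fast and locally — though not always globally — optimal. Scores are
invariant to the position of the root, and characters with fewer than
three inapplicable tokens reduce exactly to ordinary Fitch lengths.

The package also provides the two traditional treatments (`missing`,
`extra_state`) behind the same interface, a brute-force oracle that
exhaustively minimizes the same steps + regions objective on small trees,
a parsimony-ratchet tree search with NNI/SPR rearrangements, three-way
optimal-set comparison utilities (topology overlap, strict-consensus
bipartition sharing), and a seeded generator of reductively coded
character hierarchies. I/O covers NEXUS and TNT matrices and (multi-tree)
Newick.

## Worked example

A character observed in two separate regions of a ten-taxon tree: tips
`t1 t2 t3` have states `1 1 0`, tip `t4` has state `0`, and the six `c*`
tips lack the principal structure (`-`).

```python
>>> from inappfitch import score_character, ancestral_states
>>> from inappfitch.datasets import worked_example
>>> tree, column = worked_example()
>>> b = score_character(tree, column)
>>> b.steps, b.extra_regions, b.total
(1, 1, 2)
```

The single transformation is the `1 -> 0` change inside the left region;
the second, independent occurrence of state `0` at `t4` is a separate
applicable region and adds one more point, for a total contribution of 2.
Treating the gaps as missing data scores the same tree at 2 by a different
route (two steps, no regions) here, but treating inapplicability as an
extra state charges 3 — it bills the loss of the structure itself.

The same computation from the shell (`worked.tnt` / `worked.nwk` hold the
matrix and tree printed above):

```
$ inappfitch score -t worked.nwk -m worked.tnt --method inapplicable --out report.tsv
total	2
$ cat report.tsv
character	method	steps	regions	total
0	inapplicable	1	1	2
```

Simulation, search and comparison run the same way:

```
$ inappfitch simulate --taxa 12 --seed 2 -o tail        # tail.nex/.tnt/.nwk/.json
$ inappfitch score -t tail.nwk -m tail.nex --method inapplicable
total	8
$ inappfitch search -m tail.nex --method inapplicable --ratchet-iter 10 \
      --stop-after 10 --seed 1 --out best.nwk
best_score	7
```

## Acceptance script

`scripts/acceptance.py` rebuilds the worked example from the library,
runs the three scoring passes, and writes the character's total score
contribution to a JSON file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `inappfitch.statesets` — alphabets, bit-mask state sets, NEXUS/TNT I/O,
  missing-data expansion, additive-binary recoding of neomorphic
  characters
- `inappfitch.trees` — rooted trees, Newick I/O, rerooting, bipartitions,
  strict consensus, topology enumeration
- `inappfitch.inapplicable_fitch` — the four-pass scoring and
  reconstruction algorithm
- `inappfitch.baselines` — the `missing` and `extra_state` Fitch
  treatments
- `inappfitch.oracle` — exhaustive minimum of the steps + regions
  objective (test oracle)
- `inappfitch.search` — NNI/SPR neighborhoods, parsimony ratchet,
  exhaustive search
- `inappfitch.compare` — cross-scoring tables, topology-overlap tallies,
  consensus bipartition sharing
- `inappfitch.simulate` — seeded hierarchy generator
- `inappfitch.cli` — the `inappfitch` command

See `docs/methods.md` for the algorithm, its assumptions and its
numerical conventions.
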