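"""Three-way comparison of optimal tree sets across scoring methods.

Given the sets of trees found optimal under the ``inapplicable``,
``missing`` and ``extra_state`` treatments, these helpers tally how much
the sets overlap (topology-by-topology, and through the bipartitions of
their strict consensus trees) and re-score one method's optima under
another method.  All tallies identify trees by their canonical unrooted
topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .search import matrix_score
from .statesets import Matrix
from .trees import Tree, bipartitions, canonical_key, strict_consensus

__all__ = ["cross_score_table", "OverlapTally", "optimal_overlap",
           "consensus_overlap"]


def cross_score_table(trees_p: Sequence[Tree], matrix: Matrix,
                      method_q: str,
                      trees_q: Sequence[Tree] = ()) -> pd.DataFrame:
    """Score method P's optimal trees under method Q, relative to Q's best.

    The reference minimum is taken over ``trees_p`` and ``trees_q``
    together, so a relative score of 0 means the tree is also optimal
    under Q (within the supplied sets).
    """
    trees_p = list(trees_p)
    if not trees_p:
        raise DataError("empty tree set")
    taxa = frozenset(matrix.taxa)
    for t in list(trees_p) + list(trees_q):
        if t.leaf_labels() != taxa:
            raise DataError("tree leaf set does not match the matrix taxa")
    scores_p = [matrix_score(t, matrix, method_q) for t in trees_p]
    scores_q = [matrix_score(t, matrix, method_q) for t in trees_q]
    reference = min(scores_p + scores_q)
    return pd.DataFrame({
        "tree": range(len(trees_p)),
        "score": scores_p,
        "relative": [s - reference for s in scores_p],
    })


@dataclass(frozen=True)
class OverlapTally:
    """Venn counts of distinct topologies across the three optimal sets."""

    counts: Mapping[str, int]  # keys: A, B, C, AB, AC, BC, ABC

    @property
    def n_union(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_union
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}


def optimal_overlap(set_a: Iterable[Tree], set_b: Iterable[Tree],
                    set_c: Iterable[Tree]) -> OverlapTally:
    """Tally topologies optimal under exactly one, two, or all three
    methods."""
    keys = [
        {canonical_key(t) for t in set_a},
        {canonical_key(t) for t in set_b},
        {canonical_key(t) for t in set_c},
    ]
    names = "ABC"
    counts = {}
    union = set().union(*keys)
    for k in union:
        members = "".join(names[i] for i in range(3) if k in keys[i])
        counts[members] = counts.get(members, 0) + 1
    for region in ("A", "B", "C", "AB", "AC", "BC", "ABC"):
        counts.setdefault(region, 0)
    return OverlapTally(counts)


def consensus_overlap(set_a: Sequence[Tree], set_b: Sequence[Tree],
                      set_c: Sequence[Tree]) -> dict[str, float | None]:
    """Shared strict-consensus bipartition fractions between methods.

    For each ordered pair (X, Y): the fraction of X's strict-consensus
    bipartitions also present in Y's strict consensus; ``all`` is the
    fraction of each set's bipartitions present in all three.  ``None``
    marks an undefined fraction (star-shaped consensus).
    """
    sets = {"A": list(set_a), "B": list(set_b), "C": list(set_c)}
    for name, ts in sets.items():
        if not ts:
            raise DataError(f"empty tree set {name}")
    splits = {name: bipartitions(strict_consensus(ts))
              for name, ts in sets.items()}
    out: dict[str, float | None] = {}
    for x, y in ((a, b) for a in "ABC" for b in "ABC" if a != b):
        denom = len(splits[x])
        out[f"{x}|{y}"] = (len(splits[x] & splits[y]) / denom
                           if denom else None)
    triple = splits["A"] & splits["B"] & splits["C"]
    for x in "ABC":
        denom = len(splits[x])
        out[f"{x}|all"] = len(triple) / denom if denom else None
    return out
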