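"""Brute-force evaluation of the steps + regions objective on small trees.

The objective the scoring algorithm approximates can be stated exactly on a
fully labelled tree: count one step for every edge whose endpoints hold two
distinct applicable states (edges touching an inapplicable label are free),
and count the connected components ("regions", equivalently subcharacters)
of the subgraph induced by applicable-labelled nodes; every region beyond
the first costs one.  :func:`min_cost` minimizes this exhaustively over all
single-state labelings, which makes it an independent test oracle.

The exhaustive minimum may connect regions through unobserved ancestors in
ways the pass rules forbid, so it is a lower bound on the algorithm's
total, not an equivalence target.
"""

from __future__ import annotations

import itertools
from typing import Mapping

from .errors import DataError, SizeLimitError
from .inapplicable_fitch import ScoreBreakdown, _prepare
from .statesets import CharacterColumn
from .trees import Node, Tree

__all__ = ["labeling_cost", "min_cost"]

_INAPP = "-"


def labeling_cost(tree: Tree, labeling: Mapping[Node, str],
                  inapplicable_symbol: str = _INAPP) -> ScoreBreakdown:
    """Cost of a fully labelled tree (one state symbol per node)."""
    nodes = tree.postorder()
    for v in nodes:
        if v not in labeling:
            raise DataError("unlabelled node")
    steps = 0
    for v in nodes:
        if v.parent is None:
            continue
        a, b = labeling[v], labeling[v.parent]
        if a != b and a != inapplicable_symbol and b != inapplicable_symbol:
            steps += 1
    # regions: connected components of applicable-labelled nodes
    regions = 0
    seen: set[int] = set()
    applicable = [v for v in nodes if labeling[v] != inapplicable_symbol]
    app_ids = {id(v) for v in applicable}
    adjacency: dict[int, list[Node]] = {id(v): [] for v in applicable}
    for v in applicable:
        if v.parent is not None and id(v.parent) in app_ids:
            adjacency[id(v)].append(v.parent)
            adjacency[id(v.parent)].append(v)
    for v in applicable:
        if id(v) in seen:
            continue
        regions += 1
        stack = [v]
        while stack:
            u = stack.pop()
            if id(u) in seen:
                continue
            seen.add(id(u))
            stack.extend(adjacency[id(u)])
    return ScoreBreakdown(steps, max(0, regions - 1))


def min_cost(tree: Tree, column: CharacterColumn, max_nodes: int = 10,
             max_combinations: int = 3_000_000
             ) -> tuple[ScoreBreakdown, dict[Node, str]]:
    """Exhaustive minimum of :func:`labeling_cost` over all labelings.

    Internal nodes range over every applicable symbol plus the inapplicable
    one; tips range over the members of their (missing-expanded) sets.
    """
    tree.require_binary()
    col = _prepare(column)
    alpha = col.alphabet
    inapp_sym = alpha.inapplicable_symbol
    internals = [v for v in tree.postorder() if not v.is_leaf]
    if len(internals) > max_nodes:
        raise SizeLimitError(
            f"{len(internals)} internal nodes exceeds max_nodes={max_nodes}")
    options: list[tuple[Node, list[str]]] = []
    for v in tree.leaves():
        opts = alpha.symbols(col.mask(v.label))
        options.append((v, opts))
    internal_opts = list(alpha.applicable_symbols) + [inapp_sym]
    for v in internals:
        options.append((v, internal_opts))
    n_comb = 1
    for _, opts in options:
        n_comb *= len(opts)
    if n_comb > max_combinations:
        raise SizeLimitError(f"{n_comb} labelings exceed the enumeration cap")
    nodes = [v for v, _ in options]
    index = {id(v): i for i, v in enumerate(nodes)}
    edge_list = [(index[id(v)], index[id(v.parent)])
                 for v in tree.postorder() if v.parent is not None]
    best: ScoreBreakdown | None = None
    best_labeling: dict[Node, str] = {}
    for combo in itertools.product(*(opts for _, opts in options)):
        steps = app_edges = 0
        for i, j in edge_list:
            a, b = combo[i], combo[j]
            if a == inapp_sym or b == inapp_sym:
                continue
            if a != b:
                steps += 1
            app_edges += 1
        n_app = sum(1 for s in combo if s != inapp_sym)
        # components of a forest = vertices - edges
        extra = max(0, (n_app - app_edges) - 1)
        total = steps + extra
        if best is None or total < best.total:
            best = ScoreBreakdown(steps, extra)
            best_labeling = dict(zip(nodes, combo))
    assert best is not None
    return best, best_labeling
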