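"""Heuristic maximum-parsimony search (parsimony ratchet) and rearrangements.

The ratchet alternates hill climbing under perturbed character weights (a
random fraction of characters doubled) with hill climbing under the
original weights, escaping local optima while retaining every distinct
topology that attains the best original-weight score.  Any of the three
scoring methods (``inapplicable``, ``missing``, ``extra_state``) can drive
the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import baselines
from .errors import StructureError
from .inapplicable_fitch import score_character
from .statesets import CharacterColumn, Matrix
from .trees import (Node, Tree, canonical_key, edges, enumerate_topologies,
                    random_tree)

__all__ = [
    "METHODS",
    "character_length",
    "matrix_score",
    "nni_neighbors",
    "spr_neighbors",
    "SearchConfig",
    "TreeSet",
    "ratchet_search",
    "exhaustive_search",
]

METHODS = ("inapplicable", "missing", "extra_state")


def character_length(tree: Tree, column: CharacterColumn, method: str) -> int:
    """Score of one character under one of the three treatments."""
    if method == "inapplicable":
        return score_character(tree, column).total
    if method == "missing":
        return baselines.fitch_missing_length(tree, column)
    if method == "extra_state":
        return baselines.fitch_extra_state_length(tree, column)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def matrix_score(tree: Tree, matrix: Matrix, method: str,
                 weights: Sequence[int] | None = None) -> int:
    """Weighted sum of per-character scores under ``method``."""
    if weights is None:
        weights = [1] * matrix.n_characters
    return sum(w * character_length(tree, col, method)
               for w, col in zip(weights, matrix.columns))


# ---------------------------------------------------------------------------
# rearrangements

def nni_neighbors(tree: Tree) -> list[Tree]:
    """All topologies one nearest-neighbor interchange away (deduplicated,
    input excluded); two per internal edge of the unrooted topology."""
    tree.require_binary()
    if tree.n_leaves < 4:
        raise StructureError("NNI needs at least 4 leaves")
    own = canonical_key(tree)
    out: dict = {}

    def swapped(a, b):
        new, mapping = tree.copy_with_map()
        x, y = mapping[a], mapping[b]
        px, py = x.parent, y.parent
        px.children[px.children.index(x)] = y
        py.children[py.children.index(y)] = x
        x.parent, y.parent = py, px
        return new

    for v in tree.postorder():
        if v.is_leaf or v.parent is None:
            continue
        p = v.parent
        sib = p.children[0] if p.children[1] is v else p.children[1]
        if p.parent is None:
            # the two root-child edges form one unrooted edge; swap across
            # it once, exchanging grandchildren
            if v is p.children[1] or sib.is_leaf:
                continue
            partners = sib.children
            anchor = v.children[1]
            candidates = [(anchor, c) for c in partners]
        else:
            candidates = [(sib, c) for c in v.children]
        for a, b in candidates:
            new = swapped(a, b)
            key = canonical_key(new)
            if key != own:
                out[key] = new
    return list(out.values())


def spr_neighbors(tree: Tree) -> list[Tree]:
    """All subtree-prune-regraft rearrangements (deduplicated, input
    excluded); a superset of the NNI neighborhood."""
    tree.require_binary()
    if tree.n_leaves < 4:
        raise StructureError("SPR needs at least 4 leaves")
    own = canonical_key(tree)
    originals = [v for v in tree.postorder() if v.parent is not None]
    out: dict = {}
    for prune in originals:
        new, mapping = tree.copy_with_map()
        v = mapping[prune]
        p = v.parent
        sib = p.children[0] if p.children[1] is v else p.children[1]
        # detach v, splice out its degree-2 parent
        if p.parent is None:
            sib.parent = None
            rest_root = sib
        else:
            gp = p.parent
            gp.children[gp.children.index(p)] = sib
            sib.parent = gp
            rest_root = new.root
        rest = Tree(rest_root)
        for target in edges(rest):
            joint = Node(None)
            tp = target.parent
            tp.children[tp.children.index(target)] = joint
            joint.parent = tp
            joint.children = [target, v]
            target.parent = joint
            v.parent = joint
            key = canonical_key(Tree(rest_root))
            if key != own and key not in out:
                out[key] = Tree(rest_root).copy()
            # undo the regraft
            tp.children[tp.children.index(joint)] = target
            target.parent = tp
            joint.children = []
            v.parent = None
    return list(out.values())


_NEIGHBORHOODS: dict[str, Callable[[Tree], list[Tree]]] = {
    "nni": nni_neighbors,
    "spr": spr_neighbors,
}


# ---------------------------------------------------------------------------
# ratchet

@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the ratchet search."""

    method: str = "inapplicable"
    ratchet_iterations: int = 50
    perturb_fraction: float = 0.25
    rearrangement: str = "nni"
    seed: int = 0
    stop_after_no_improvement: int = 250
    max_trees: int = 10_000

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.perturb_fraction < 1:
            raise ValueError("perturb_fraction must be in (0, 1)")
        if self.ratchet_iterations < 1:
            raise ValueError("at least one ratchet iteration required")
        if self.rearrangement not in _NEIGHBORHOODS:
            raise ValueError(f"unknown rearrangement {self.rearrangement!r}")


@dataclass
class TreeSet:
    """Distinct canonical topologies sharing one best score."""

    best_score: int
    trees: dict = field(default_factory=dict)  # canonical key -> Tree
    overflow: bool = False
    log: list = field(default_factory=list)  # per-iteration best scores

    def add(self, tree: Tree, cap: int) -> None:
        key = canonical_key(tree)
        if key in self.trees:
            return
        if len(self.trees) >= cap:
            self.overflow = True
            return
        self.trees[key] = tree

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees.values())


def _hill_climb(tree: Tree, score_fn, neighbor_fn,
                plateau_cap: int = 200) -> tuple[Tree, int]:
    """Greedy descent that walks equal-score plateaus (bounded) in search
    of an improving exit before giving up."""
    best, best_score = tree, score_fn(tree)
    while True:
        island = {canonical_key(best): best}
        frontier = [best]
        improved = None
        while frontier and improved is None:
            nxt = []
            for t in frontier:
                for nb in neighbor_fn(t):
                    s = score_fn(nb)
                    if s < best_score:
                        improved, best_score = nb, s
                        break
                    if s == best_score and len(island) < plateau_cap:
                        key = canonical_key(nb)
                        if key not in island:
                            island[key] = nb
                            nxt.append(nb)
                if improved is not None:
                    break
            frontier = nxt
        if improved is None:
            return best, best_score
        best = improved


def _collect_plateau(seed_tree: Tree, score: int, score_fn, neighbor_fn,
                     treeset: TreeSet, cap: int) -> None:
    """Breadth-first sweep over equal-score neighbors (the tree island)."""
    treeset.add(seed_tree, cap)
    frontier = [seed_tree]
    while frontier and not treeset.overflow:
        nxt = []
        for t in frontier:
            for nb in neighbor_fn(t):
                key = canonical_key(nb)
                if key in treeset.trees:
                    continue
                if score_fn(nb) == score:
                    treeset.add(nb, cap)
                    if treeset.overflow:
                        return
                    nxt.append(nb)
        frontier = nxt


def ratchet_search(matrix: Matrix, config: SearchConfig) -> TreeSet:
    """Parsimony-ratchet search returning all best-score topologies found."""
    rng = np.random.default_rng(config.seed)
    neighbor_fn = _NEIGHBORHOODS[config.rearrangement]
    method = config.method

    def score_fn(weights=None):
        return lambda t: matrix_score(t, matrix, method, weights)

    original = score_fn()
    current, _ = _hill_climb(random_tree(matrix.taxa, rng), original,
                             neighbor_fn)
    best_score = original(current)
    result = TreeSet(best_score=best_score)
    _collect_plateau(current, best_score, original, neighbor_fn, result,
                     config.max_trees)
    no_improve = 0
    n_up = max(1, round(config.perturb_fraction * matrix.n_characters))
    for _ in range(config.ratchet_iterations):
        up = set(rng.choice(matrix.n_characters, size=n_up,
                            replace=False).tolist())
        weights = [2 if j in up else 1 for j in range(matrix.n_characters)]
        perturbed_tree, _ = _hill_climb(current, score_fn(weights),
                                        neighbor_fn)
        candidate, cand_score = _hill_climb(perturbed_tree, original,
                                            neighbor_fn)
        result.log.append(min(best_score, cand_score))
        if cand_score < best_score:
            best_score = cand_score
            result = TreeSet(best_score=best_score, log=result.log)
            _collect_plateau(candidate, best_score, original, neighbor_fn,
                             result, config.max_trees)
            no_improve = 0
        else:
            if cand_score == best_score:
                _collect_plateau(candidate, best_score, original,
                                 neighbor_fn, result, config.max_trees)
            no_improve += 1
        # the working tree always follows the ratchet iteration: accepting
        # equal-or-worse local optima is what lets the search escape
        current = candidate
        if no_improve >= config.stop_after_no_improvement:
            break
    result.best_score = best_score
    return result


def exhaustive_search(matrix: Matrix, method: str,
                      max_leaves: int = 9) -> TreeSet:
    """Best score and all optimal topologies by complete enumeration."""
    if matrix.n_taxa > max_leaves:
        raise StructureError(
            f"{matrix.n_taxa} taxa exceeds enumeration cap {max_leaves}")
    best_score: int | None = None
    result = TreeSet(best_score=0)
    for t in enumerate_topologies(matrix.taxa):
        s = matrix_score(t, matrix, method)
        if best_score is None or s < best_score:
            best_score = s
            result = TreeSet(best_score=s)
            result.add(t, 1_000_000)
        elif s == best_score:
            result.add(t, 1_000_000)
    result.best_score = best_score if best_score is not None else 0
    return result
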