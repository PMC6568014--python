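"""Inapplicable-aware Fitch parsimony: four-pass scoring and reconstruction.

A character that is logically inapplicable in some taxa cannot be scored by
counting transformations alone: a tree can avoid transformations by breaking
the character into several independent *regions* of applicability (separate
origins of the principal structure), and each extra region is itself a
homoplasy.  The score of a character is therefore

    total = steps + extra_regions

where ``steps`` counts ordinary state transformations inside applicable
regions and ``extra_regions`` counts additional applicable regions beyond
the first.  The algorithm proceeds in up to four tree traversals:

1. *first downpass*  -- preliminary state sets, Fitch-like but aware of the
   inapplicable state;
2. *first uppass*    -- resolve every vertex as applicable or inapplicable
   (ambiguous vertices resolve toward applicability: parallel losses are
   preferred over loss and regain), then resolve ambiguous tips against
   their parent;
3. *second downpass* -- Fitch over applicable states within regions, adding
   steps, while a per-node boolean *tracker* detects junctions where two
   subtrees that each already contain an applicable region meet, adding
   region counts;
4. *second uppass*   -- final ancestral state sets (does not change the
   score).

Three passes score a tree; the fourth is only needed for ancestral states.
Characters with fewer than three inapplicable tokens cannot produce more
than one mandatory region and are dispatched to plain Fitch with ``-``
treated as missing data.

The method is locally optimal: on every instance its total is an upper
bound on (and usually equal to) the exhaustive minimum of the same
objective (see :mod:`inappfitch.oracle`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import baselines
from .errors import DataError
from .statesets import CharacterColumn, Matrix, StateSet, expand_missing
from .trees import Node, Tree

__all__ = [
    "ScoreBreakdown",
    "Reconstruction",
    "score_character",
    "score_matrix",
    "ancestral_states",
    "first_downpass",
    "first_uppass",
    "resolve_tips",
    "second_downpass",
    "second_uppass",
    "INAPPLICABLE_THRESHOLD",
]

#: characters with fewer inapplicable singletons than this are plain Fitch
INAPPLICABLE_THRESHOLD = 3


@dataclass(frozen=True)
class ScoreBreakdown:
    """Score of one character on one tree: transformations + extra regions."""

    steps: int
    extra_regions: int

    @property
    def total(self) -> int:
        return self.steps + self.extra_regions

    def __add__(self, other: "ScoreBreakdown") -> "ScoreBreakdown":
        return ScoreBreakdown(self.steps + other.steps,
                              self.extra_regions + other.extra_regions)


# ---------------------------------------------------------------------------
# node-local pass rules (unit-testable against the published worked cases)

def down1(left: int, right: int, inapp: int, full_app: int) -> int:
    """First-downpass set for a node from its children's sets."""
    l_app, r_app = left & full_app, right & full_app
    l_in, r_in = left & inapp, right & inapp
    if l_app and r_app and not (l_in and r_in):
        # both children applicable-bearing, at most one inapplicable-bearing
        common = l_app & r_app
        return common if common else (l_app | r_app)
    if l_in and r_in and not (l_app and r_app):
        return inapp
    return left | right


def down2(applicable: bool, lw: int, rw: int, lt: bool, rt: bool,
          fallback: int, inapp: int, full_app: int) -> tuple[int, int, int]:
    """Second-downpass working set and (step, region) increments."""
    if not applicable:
        return inapp, 0, 1 if (lt and rt) else 0
    l_app, r_app = lw & full_app, rw & full_app
    common = l_app & r_app
    if common:
        return common, 0, 0
    if l_app and r_app:
        return l_app | r_app, 1, 0
    working = l_app | r_app
    if not working:
        working = fallback & full_app
    return working, 0, 1 if (lt and rt) else 0


def up2(working: int, anc_final: int, l_working: int, r_working: int,
        inapp: int, full_app: int) -> int:
    """Second-uppass (final) set of an applicable node whose ancestor is
    applicable; standard Fitch final-state rules on applicable states."""
    f = anc_final & full_app
    if f & working == f:
        return f
    l_app, r_app = l_working & full_app, r_working & full_app
    if l_app and r_app and (l_app & r_app):
        return working | (f & (l_app | r_app))
    return working | f


# ---------------------------------------------------------------------------
# full passes

def _check_tree_column(tree: Tree, column: CharacterColumn) -> None:
    tree.require_binary()
    leaves = tree.leaf_labels()
    missing = set(column.states) - leaves
    if missing:
        raise DataError(f"taxa absent from tree: {sorted(missing)}")
    absent = leaves - set(column.states)
    if absent:
        raise DataError(f"no states for leaves: {sorted(absent)}")


def _tip_mask(column: CharacterColumn, label: str) -> int:
    mask = column.states[label].mask
    if mask == 0:
        raise DataError(f"unexpanded missing cell at {label!r}; "
                        "run expand_missing first")
    return mask


def first_downpass(tree: Tree, column: CharacterColumn) -> dict[Node, int]:
    """Preliminary state sets, post-order."""
    _check_tree_column(tree, column)
    alpha = column.alphabet
    inapp, full_app = alpha.inapplicable_bit, alpha.full_applicable
    prelim: dict[Node, int] = {}
    for v in tree.postorder():
        if v.is_leaf:
            prelim[v] = _tip_mask(column, v.label)
        else:
            l, r = (prelim[c] for c in v.children)
            prelim[v] = down1(l, r, inapp, full_app)
    return prelim


def first_uppass(tree: Tree, column: CharacterColumn,
                 prelim: Mapping[Node, int]
                 ) -> tuple[dict[Node, int], dict[Node, bool]]:
    """Resolve each internal vertex as applicable or inapplicable, pre-order.

    A vertex with a purely applicable preliminary set stays applicable.  A
    vertex with a *mixed* preliminary set resolves with its ancestor:
    applicable ancestor -> keep the applicable states, inapplicable
    ancestor -> inapplicable; the root's phantom ancestor counts as
    applicable, so mixed ambiguity at the root resolves toward presence
    (parallel losses are preferred over loss and regain).  A non-root
    vertex whose set is exactly the inapplicable singleton but whose
    ancestor is applicable becomes applicable if its children offer
    applicable states (two of its three neighbours are then applicable);
    at the root, which has only a phantom ancestor, the inapplicable
    singleton is final.
    """
    alpha = column.alphabet
    inapp, full_app = alpha.inapplicable_bit, alpha.full_applicable
    upset: dict[Node, int] = {}
    flag: dict[Node, bool] = {}
    for v in tree.preorder():
        if v.is_leaf:
            continue
        own = prelim[v] & full_app
        if v.parent is None:
            if own:
                flag[v], upset[v] = True, own
            else:
                flag[v], upset[v] = False, inapp
            continue
        anc_app = flag[v.parent]
        if own and not (prelim[v] & inapp):
            flag[v], upset[v] = True, own
        elif own:  # mixed preliminary set
            if anc_app:
                flag[v], upset[v] = True, own
            else:
                flag[v], upset[v] = False, inapp
        else:  # inapplicable singleton
            l, r = v.children
            kids = (prelim[l] | prelim[r]) & full_app
            if anc_app and kids:
                flag[v], upset[v] = True, kids
            else:
                flag[v], upset[v] = False, inapp
    return upset, flag


def resolve_tips(tree: Tree, column: CharacterColumn,
                 flag: Mapping[Node, bool]) -> dict[Node, int]:
    """Resolve ambiguous tips (both applicable and inapplicable states)
    toward their parent's applicability; returns the resolved tip masks."""
    alpha = column.alphabet
    inapp, full_app = alpha.inapplicable_bit, alpha.full_applicable
    resolved: dict[Node, int] = {}
    for v in tree.leaves():
        m = _tip_mask(column, v.label)
        if (m & full_app) and (m & inapp):
            m = (m & full_app) if flag[v.parent] else inapp
        resolved[v] = m
    return resolved


def second_downpass(tree: Tree, column: CharacterColumn,
                    upset: Mapping[Node, int], flag: Mapping[Node, bool],
                    resolved_tips: Mapping[Node, int]
                    ) -> tuple[dict[Node, int], ScoreBreakdown]:
    """Fitch within applicable regions; counts steps and extra regions."""
    alpha = column.alphabet
    inapp, full_app = alpha.inapplicable_bit, alpha.full_applicable
    working: dict[Node, int] = {}
    tracker: dict[Node, bool] = {}
    steps = regions = 0
    for v in tree.postorder():
        if v.is_leaf:
            working[v] = resolved_tips[v]
            tracker[v] = bool(working[v] & full_app)
            continue
        l, r = v.children
        w, dstep, dregion = down2(flag[v], working[l], working[r],
                                  tracker[l], tracker[r], upset[v],
                                  inapp, full_app)
        working[v] = w
        steps += dstep
        regions += dregion
        tracker[v] = tracker[l] or tracker[r]
    return working, ScoreBreakdown(steps, regions)


def second_uppass(tree: Tree, column: CharacterColumn,
                  working: Mapping[Node, int], flag: Mapping[Node, bool]
                  ) -> dict[Node, int]:
    """Final ancestral state sets; never changes the score."""
    alpha = column.alphabet
    inapp, full_app = alpha.inapplicable_bit, alpha.full_applicable
    final: dict[Node, int] = {}
    for v in tree.preorder():
        if v.is_leaf:
            final[v] = working[v]
            continue
        if not flag[v]:
            final[v] = inapp
            continue
        if v.parent is None or final[v.parent] == inapp:
            final[v] = working[v]
            continue
        l, r = v.children
        final[v] = up2(working[v], final[v.parent], working[l], working[r],
                       inapp, full_app)
    return final


# ---------------------------------------------------------------------------
# public scoring API

@dataclass(frozen=True)
class Reconstruction:
    """Ancestral reconstruction of one character on one tree."""

    tree: Tree
    column: CharacterColumn
    final: Mapping[Node, int]
    breakdown: ScoreBreakdown

    def state_set(self, node: Node) -> StateSet:
        return StateSet(self.column.alphabet, self.final[node])

    def as_rows(self) -> list[tuple[int, str, str]]:
        """(node index, leaf label or '', state tokens) in preorder."""
        out = []
        for i, v in enumerate(self.tree.preorder()):
            syms = "".join(self.column.alphabet.symbols(self.final[v]))
            out.append((i, v.label or "", syms))
        return out


def _prepare(column: CharacterColumn) -> CharacterColumn:
    return expand_missing(column, "all_states") if column.has_missing else column


def score_character(tree: Tree, column: CharacterColumn) -> ScoreBreakdown:
    """Score one character on a binary tree (three passes).

    Characters with fewer than :data:`INAPPLICABLE_THRESHOLD` inapplicable
    singletons are scored by plain Fitch with ``-`` treated as missing.
    """
    col = _prepare(column)
    if col.n_inapplicable < INAPPLICABLE_THRESHOLD:
        return ScoreBreakdown(baselines.fitch_missing_length(tree, col), 0)
    prelim = first_downpass(tree, col)
    upset, flag = first_uppass(tree, col, prelim)
    tips = resolve_tips(tree, col, flag)
    _, breakdown = second_downpass(tree, col, upset, flag, tips)
    return breakdown


def score_matrix(tree: Tree, matrix: Matrix,
                 weights: Sequence[int] | None = None
                 ) -> tuple[int, list[ScoreBreakdown]]:
    """Sum of per-character totals (optionally weighted)."""
    if weights is None:
        weights = [1] * matrix.n_characters
    if len(weights) != matrix.n_characters:
        raise DataError("one weight per character required")
    breakdowns = [score_character(tree, col) for col in matrix.columns]
    total = sum(w * b.total for w, b in zip(weights, breakdowns))
    return total, breakdowns


def ancestral_states(tree: Tree, column: CharacterColumn) -> Reconstruction:
    """Run all four passes; the reported score equals :func:`score_character`."""
    col = _prepare(column)
    if col.n_inapplicable < INAPPLICABLE_THRESHOLD:
        masks = baselines.missing_masks(col)
        _, final, length = baselines.fitch_sets(tree, masks)
        return Reconstruction(tree, col, final, ScoreBreakdown(length, 0))
    prelim = first_downpass(tree, col)
    upset, flag = first_uppass(tree, col, prelim)
    tips = resolve_tips(tree, col, flag)
    working, breakdown = second_downpass(tree, col, upset, flag, tips)
    final = second_uppass(tree, col, working, flag)
    return Reconstruction(tree, col, final, breakdown)
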