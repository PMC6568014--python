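"""Traditional Fitch treatments of inapplicable tokens.

Both treatments run the same Fitch engine and differ only in how the gap
and missing tokens map onto state sets:

* ``missing``      -- ``-`` and ``?`` both become "any applicable state".
* ``extra_state``  -- ``-`` is an ordinary (k+1)-th state; ``?`` spans all
  k+1 states.

Neither counts applicable regions, so their :class:`ScoreBreakdown` always
has ``extra_regions == 0``.
"""

from __future__ import annotations

from .errors import DataError
from .statesets import CharacterColumn
from .trees import Tree

__all__ = [
    "fitch_length",
    "fitch_missing_length",
    "fitch_extra_state_length",
    "missing_masks",
    "extra_state_masks",
]


def _tip_masks(tree: Tree, masks: dict[str, int]) -> None:
    missing = set(masks) - tree.leaf_labels()
    if missing:
        raise DataError(f"taxa absent from tree: {sorted(missing)}")


def fitch_length(tree: Tree, masks: dict[str, int]) -> int:
    """Standard Fitch downpass length (number of union events)."""
    tree.require_binary()
    _tip_masks(tree, masks)
    length = 0
    down: dict = {}
    for v in tree.postorder():
        if v.is_leaf:
            try:
                down[v] = masks[v.label]
            except KeyError:
                raise DataError(f"no state for leaf {v.label!r}") from None
            if down[v] == 0:
                raise DataError(f"empty state set at leaf {v.label!r}")
        else:
            l, r = (down[c] for c in v.children)
            inter = l & r
            if inter:
                down[v] = inter
            else:
                down[v] = l | r
                length += 1
    return length


def fitch_sets(tree: Tree, masks: dict[str, int]) -> tuple[dict, dict, int]:
    """Fitch downpass and uppass state sets plus the length."""
    tree.require_binary()
    _tip_masks(tree, masks)
    length = 0
    down: dict = {}
    for v in tree.postorder():
        if v.is_leaf:
            down[v] = masks[v.label]
        else:
            l, r = (down[c] for c in v.children)
            down[v] = l & r
            if not down[v]:
                down[v] = l | r
                length += 1
    final: dict = {}
    for v in tree.preorder():
        if v.is_leaf:
            final[v] = down[v]
            continue
        if v.parent is None:
            final[v] = down[v]
            continue
        fp = final[v.parent]
        dv = down[v]
        if fp & dv == fp:
            final[v] = fp
        else:
            dl, dr = (down[c] for c in v.children)
            if dl & dr:
                final[v] = dv | (fp & (dl | dr))
            else:
                final[v] = dv | fp
    return down, final, length


def missing_masks(column: CharacterColumn) -> dict[str, int]:
    """Tip masks under the "missing" treatment (gap == unknown)."""
    alpha = column.alphabet
    full = alpha.full_applicable
    out = {}
    for taxon, s in column.states.items():
        app = s.mask & full
        out[taxon] = app if app else full
    return out


def extra_state_masks(column: CharacterColumn) -> dict[str, int]:
    """Tip masks under the "extra state" treatment (gap == its own state)."""
    alpha = column.alphabet
    out = {}
    for taxon, s in column.states.items():
        out[taxon] = alpha.full if s.is_missing else s.mask
    return out


def fitch_missing_length(tree: Tree, column: CharacterColumn) -> int:
    """Fitch length treating inapplicable tokens as missing data."""
    return fitch_length(tree, missing_masks(column))


def fitch_extra_state_length(tree: Tree, column: CharacterColumn) -> int:
    """Fitch length treating inapplicability as a separate character state."""
    return fitch_length(tree, extra_state_masks(column))
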