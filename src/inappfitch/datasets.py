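"""Small built-in examples."""

from __future__ import annotations

from .statesets import CharacterColumn, column_from_tokens
from .trees import Tree, parse_newick

__all__ = ["worked_example", "two_region_example"]


def worked_example() -> tuple[Tree, CharacterColumn]:
    """The canonical two-region worked example.

    A principal structure is present in two separate parts of the tree.
    Inside the left region the dependent character transforms once (1 -> 0);
    the right region shows a second, independent occurrence of state 0.
    The character therefore contributes 2 to the tree score: one step plus
    one additional applicable region.
    """
    tree = parse_newick(
        "((((t1,(t2,t3)),c5),(c6,c7)),((c8,c9),(t4,c10)));"
    )
    taxa = ["t1", "t2", "t3", "c5", "c6", "c7", "c8", "c9", "t4", "c10"]
    tokens = ["1", "1", "0", "-", "-", "-", "-", "-", "0", "-"]
    return tree, column_from_tokens(taxa, tokens, label="tail colour")


def two_region_example() -> tuple[Tree, CharacterColumn]:
    """Eight tips, two single-tip applicable regions joined at an
    inapplicable root: no steps, one additional region (total 1)."""
    tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    taxa = list("ABCDEFGH")
    tokens = ["0", "-", "-", "-", "-", "-", "0", "-"]
    return tree, column_from_tokens(taxa, tokens)
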