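"""Shared fixtures: random instances and an independent Fitch oracle."""

from __future__ import annotations

import numpy as np
import pytest

from inappfitch import column_from_tokens, random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_instance(rng, n, symbols=("0", "1", "-", "-", "?"), prefix="x"):
    """One random (tree, column) pair on n taxa."""
    labels = [f"{prefix}{i}" for i in range(n)]
    tree = random_tree(labels, rng)
    tokens = [str(rng.choice(list(symbols))) for _ in range(n)]
    return tree, column_from_tokens(labels, tokens), tokens


def textbook_fitch(tree, masks):
    """Independent recursive Fitch length (test oracle only)."""

    def rec(v):
        if v.is_leaf:
            return masks[v.label], 0
        (lm, lc), (rm, rc) = (rec(c) for c in v.children)
        inter = lm & rm
        if inter:
            return inter, lc + rc
        return lm | rm, lc + rc + 1

    _, cost = rec(tree.root)
    return cost
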