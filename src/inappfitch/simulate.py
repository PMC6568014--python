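"""Synthetic trees and reductively coded character hierarchies.

The generator emulates the coding structure the scoring algorithm assumes:
a principal presence/absence character evolving on a known tree, plus
dependent characters that only exist while the principal structure is
present and are emitted as ``-`` (inapplicable) wherever it is absent.
Topologies follow a Yule (random leaf split) process with unit branch
lengths, and states evolve by continuous-time Markov chains: a two-state
gain/loss chain for the principal character and a symmetric chain over the
dependent states along applicable lineages (a regained structure draws its
dependent state afresh).  Optionally a uniform fraction of cells is
replaced by ``?`` afterwards.

This is deliberately the simplest generative model with the stated coding
structure, not a realistic model of morphological evolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import StructureError
from .statesets import CharacterColumn, Matrix, column_from_tokens
from .trees import Node, Tree

__all__ = ["HierarchySpec", "simulate_tree", "simulate_hierarchy"]


@dataclass(frozen=True)
class HierarchySpec:
    """Parameters of one synthetic character hierarchy.

    Rates are per unit branch length (all branches have length 1).
    ``principal_gain_loss_rates`` are the gain (0->1) and loss (1->0) rates
    of the principal presence/absence character; ``dependent_rate`` is the
    total leaving rate of each dependent character's symmetric chain.
    """

    n_taxa: int = 16
    principal_gain_loss_rates: tuple[float, float] = (0.2, 0.2)
    n_dependent: int = 3
    n_dependent_states: int = 2
    dependent_rate: float = 0.3
    missing_rate: float = 0.0
    neomorphic_dependent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise StructureError("need at least 4 taxa")
        if min(self.principal_gain_loss_rates) <= 0 or self.dependent_rate <= 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_dependent_states < 2:
            raise ValueError("dependent characters need >= 2 states")
        if self.neomorphic_dependent and self.n_dependent_states != 2:
            raise ValueError("neomorphic dependents are presence/absence "
                             "(2 states)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def simulate_tree(n_taxa: int, seed: int | np.random.Generator) -> Tree:
    """Random rooted binary tree on taxa t1..tn (Yule split order)."""
    if n_taxa < 4:
        raise StructureError("need at least 4 taxa")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    root = Node(None, [Node(labels[0]), Node(labels[1])])
    tree = Tree(root)
    for lbl in labels[2:]:
        leaf = tree.leaves()[rng.integers(tree.n_leaves)]
        old = Node(leaf.label)
        leaf.label = None
        leaf.add(old)
        leaf.add(Node(lbl))
    return Tree(tree.root)


def _transition_matrix(q: np.ndarray) -> np.ndarray:
    return expm(q)  # unit branch lengths


def simulate_hierarchy(tree: Tree, spec: HierarchySpec) -> Matrix:
    """Evolve one principal and ``n_dependent`` dependent characters.

    With ``missing_rate == 0`` a dependent cell is ``-`` exactly where the
    principal cell is 0.
    """
    tree.require_binary()
    rng = np.random.default_rng(spec.seed)
    gain, loss = spec.principal_gain_loss_rates
    q_p = np.array([[-gain, gain], [loss, -loss]])
    p_principal = _transition_matrix(q_p)
    k = spec.n_dependent_states
    q_d = np.full((k, k), spec.dependent_rate / (k - 1))
    np.fill_diagonal(q_d, -spec.dependent_rate)
    p_dependent = _transition_matrix(q_d)
    stationary_present = gain / (gain + loss)

    nodes = tree.preorder()
    principal: dict[Node, int] = {}
    for v in nodes:
        if v.parent is None:
            principal[v] = int(rng.random() < stationary_present)
        else:
            principal[v] = int(rng.random()
                               < p_principal[principal[v.parent], 1])

    dep_states: list[dict[Node, int | None]] = []
    for _ in range(spec.n_dependent):
        states: dict[Node, int | None] = {}
        for v in nodes:
            if not principal[v]:
                states[v] = None
            elif v.parent is None or states[v.parent] is None:
                states[v] = int(rng.integers(k))  # origin or regain: fresh
            else:
                states[v] = int(rng.choice(k, p=p_dependent[states[v.parent]]))
        dep_states.append(states)

    leaves = tree.leaves()
    taxa = [v.label for v in leaves]
    columns: list[CharacterColumn] = []
    tokens = [str(principal[v]) for v in leaves]
    columns.append(column_from_tokens(taxa, tokens, label="principal"))
    for j, states in enumerate(dep_states):
        tokens = ["-" if states[v] is None else str(states[v])
                  for v in leaves]
        kind = "neomorphic" if spec.neomorphic_dependent else "transformational"
        columns.append(column_from_tokens(taxa, tokens,
                                          label=f"dependent_{j + 1}_{kind}"))

    if spec.missing_rate > 0:
        masked = []
        for col in columns:
            toks = []
            for v in leaves:
                if rng.random() < spec.missing_rate:
                    toks.append("?")
                else:
                    toks.append(col.states[v.label].token())
            masked.append(column_from_tokens(taxa, toks, col.alphabet,
                                             col.label))
        columns = masked
    return Matrix(tuple(taxa), tuple(columns))
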