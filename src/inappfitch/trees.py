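"""Rooted trees, Newick I/O, rerooting, bipartitions and strict consensus.

Parsimony scoring in this package uses topology only: edge lengths and
internal labels are parsed but ignored.  Trees are rooted for traversal, but
the quantities of interest (score, bipartitions, topology identity) are
invariant to the rooting, so canonical tree identity is the set of
nontrivial bipartitions of the unrooted topology.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

from .errors import StructureError, TreeParseError

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "parse_newick_trees",
    "reroot",
    "bipartitions",
    "strict_consensus",
    "canonical_key",
    "resolve_polytomies",
    "enumerate_topologies",
    "random_tree",
]


class Node:
    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None,
                 children: Sequence["Node"] = ()) -> None:
        self.label = label
        self.children: list[Node] = list(children)
        self.parent: Node | None = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'}>"


class Tree:
    """A rooted tree over uniquely labelled leaves."""

    def __init__(self, root: Node) -> None:
        self.root = root
        labels = [v.label for v in self.leaves()]
        if len(set(labels)) != len(labels):
            raise TreeParseError("duplicate leaf labels")
        if any(lbl is None for lbl in labels):
            raise TreeParseError("unlabelled leaf")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(v.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(v.children))
        return out

    def leaves(self) -> list[Node]:
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(v.children) in (0, 2) for v in self.postorder())

    def require_binary(self) -> None:
        if not self.is_binary():
            raise StructureError("operation requires a strictly binary tree")

    # -- copying -----------------------------------------------------------
    def copy(self) -> "Tree":
        return Tree(self._copy_node(self.root))

    def copy_with_map(self) -> tuple["Tree", dict[Node, Node]]:
        mapping: dict[Node, Node] = {}
        new = self._copy_node(self.root, mapping)
        return Tree(new), mapping

    @staticmethod
    def _copy_node(v: Node, mapping: dict[Node, Node] | None = None) -> Node:
        new = Node(v.label, [Tree._copy_node(c, mapping) for c in v.children])
        if mapping is not None:
            mapping[v] = new
        return new

    # -- output ------------------------------------------------------------
    def newick(self) -> str:
        def fmt(v: Node) -> str:
            if v.is_leaf:
                return _quote(v.label)
            return "(" + ",".join(fmt(c) for c in v.children) + ")"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.newick()})"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)

def _from_dendropy(dtree) -> Tree:
    def conv(dnode) -> Node:
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise TreeParseError("unlabelled leaf in Newick input")
            return Node(label)
        return Node(None, [conv(c) for c in dnode.child_nodes()])

    return Tree(conv(dtree.seed_node))


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree; polytomies are accepted at parse time."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeParseError(f"Newick parse failed: {exc}") from exc
    return _from_dendropy(dtree)


def parse_newick_trees(text: str) -> list[Tree]:
    """Parse a multi-tree Newick file (one tree per statement)."""
    import dendropy

    try:
        dtrees = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeParseError(f"Newick parse failed: {exc}") from exc
    return [_from_dendropy(t) for t in dtrees]


def write_newick_trees(trees: Iterable[Tree]) -> str:
    return "\n".join(t.newick() for t in trees) + "\n"


# ---------------------------------------------------------------------------
# rerooting

def edges(tree: Tree) -> list[Node]:
    """All edges of the rooted tree, identified by their child endpoint."""
    return [v for v in tree.postorder() if v.parent is not None]


def reroot(tree: Tree, edge_child: Node) -> Tree:
    """Return a new tree rooted on the edge above ``edge_child``.

    The unrooted topology (and hence the bipartition set) is unchanged; the
    new root subdivides the chosen edge.
    """
    if edge_child is None or _find(tree, edge_child) is None:
        raise StructureError("edge does not belong to this tree")
    if edge_child.parent is None:
        return tree.copy()

    copied, mapping = tree.copy_with_map()
    v = mapping[edge_child]

    def invert(p: Node, coming_from: Node) -> Node:
        kids = [c for c in p.children if c is not coming_from]
        if p.parent is None:  # old root: splice it out if it becomes degree-1
            if len(kids) == 1:
                kids[0].parent = None
                return kids[0]
            return Node(None, kids)
        return Node(None, kids + [invert(p.parent, p)])

    up = invert(v.parent, v)
    v.parent = None
    return Tree(Node(None, [v, up]))


def _find(tree: Tree, node: Node) -> Node | None:
    for v in tree.postorder():
        if v is node:
            return v
    return None


def all_rootings(tree: Tree) -> list[Tree]:
    """Reroot on every edge (one tree per edge; root-child edges coincide)."""
    return [reroot(tree, e) for e in edges(tree)]


# ---------------------------------------------------------------------------
# bipartitions / identity / consensus

def _leafsets(tree: Tree) -> dict[Node, frozenset[str]]:
    sets: dict[Node, frozenset[str]] = {}
    for v in tree.postorder():
        if v.is_leaf:
            sets[v] = frozenset((v.label,))
        else:
            sets[v] = frozenset().union(*(sets[c] for c in v.children))
    return sets


def bipartitions(tree: Tree) -> frozenset[frozenset[str]]:
    """Nontrivial splits of the unrooted topology.

    Each split is stored as the side *not* containing the reference taxon
    (the lexicographically smallest leaf label); a binary n-leaf tree yields
    n - 3 of them.
    """
    leaves = tree.leaf_labels()
    ref = min(leaves)
    sets = _leafsets(tree)
    out = set()
    for v in tree.postorder():
        if v.is_leaf or v.parent is None:
            continue
        side = sets[v]
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return frozenset(out)


def canonical_key(tree: Tree) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
    """Canonical identity of the unrooted topology (leaves + split set)."""
    return (tree.leaf_labels(), bipartitions(tree))


def rooted_key(tree: Tree):
    """Canonical identity of the rooted shape (nested frozensets)."""

    def key(v: Node):
        if v.is_leaf:
            return v.label
        return frozenset(key(c) for c in v.children)

    return key(tree.root)


def tree_from_clusters(leaves: Iterable[str],
                       clusters: Iterable[frozenset[str]]) -> Tree:
    """Build a rooted tree whose internal edges realise the given nested
    clusters (used by strict consensus)."""
    root = Node(None, [Node(lbl) for lbl in sorted(leaves)])
    for cluster in sorted(set(clusters), key=len, reverse=True):
        node = root
        while True:
            sets = _leafsets(Tree(node))  # local leafsets below `node`
            sup = [c for c in node.children
                   if cluster < sets[c] or cluster == sets[c]]
            if sup and sets[sup[0]] != cluster:
                node = sup[0]
                continue
            if sup:  # cluster already present
                break
            grouped = [c for c in node.children if sets[c] <= cluster]
            if frozenset().union(*(sets[c] for c in grouped)) != cluster:
                raise StructureError("incompatible clusters")
            for c in grouped:
                node.children.remove(c)
            node.add(Node(None, grouped))
            break
    return Tree(root)


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the bipartitions shared by every input tree."""
    if not trees:
        raise ValueError("strict consensus of an empty collection")
    leafsets = {t.leaf_labels() for t in trees}
    if len(leafsets) != 1:
        raise StructureError("trees do not share one leaf set")
    leaves = leafsets.pop()
    ref = min(leaves)
    shared = frozenset.intersection(*(bipartitions(t) for t in trees))
    # splits are stored as the side away from `ref`; those sides nest
    return tree_from_clusters(leaves, shared)


# ---------------------------------------------------------------------------
# shapes

def resolve_polytomies(tree: Tree, rng) -> Tree:
    """Randomly resolve every polytomy into an arbitrary binary subtree."""
    new = tree.copy()
    for v in new.postorder():
        while len(v.children) > 2:
            i, j = sorted(rng.choice(len(v.children), size=2, replace=False))
            a, b = v.children[i], v.children[j]
            v.children.remove(a)
            v.children.remove(b)
            v.add(Node(None, [a, b]))
    return new


def random_tree(labels: Sequence[str], rng) -> Tree:
    """Random rooted binary tree by a Yule (random leaf split) process."""
    labels = list(labels)
    if len(labels) < 2:
        raise StructureError("need at least two leaves")
    order = list(rng.permutation(len(labels)))
    root = Node(None, [Node(labels[order[0]]), Node(labels[order[1]])])
    tree = Tree(root)
    for idx in order[2:]:
        leaf = tree.leaves()[rng.integers(tree.n_leaves)]
        old = Node(leaf.label)
        leaf.label = None
        leaf.children = []
        leaf.add(old)
        leaf.add(Node(labels[idx]))
    return Tree(tree.root)


def enumerate_topologies(labels: Sequence[str]) -> Iterator[Tree]:
    """All distinct unrooted binary topologies, one rooted representative
    each ((2n-5)!! trees); intended for small n only."""
    labels = list(labels)
    if len(labels) < 3:
        yield Tree(Node(None, [Node(l) for l in labels]))
        return

    def insertion_edges(tree: Tree) -> list[Node]:
        # the two root-child edges are one unrooted edge: skip one of them
        return [e for e in edges(tree)
                if not (e.parent is tree.root and e is tree.root.children[0])]

    def grow(tree: Tree, remaining: list[str]) -> Iterator[Tree]:
        if not remaining:
            yield tree
            return
        lbl, rest = remaining[0], remaining[1:]
        for e in insertion_edges(tree):
            new, mapping = tree.copy_with_map()
            u = mapping[e]
            p = u.parent
            slot = p.children.index(u)
            joint = Node(None, [u, Node(lbl)])
            p.children[slot] = joint
            joint.parent = p
            yield from grow(Tree(new.root), rest)

    base = Tree(Node(None, [Node(labels[0]),
                            Node(None, [Node(labels[1]), Node(labels[2])])]))
    if len(labels) == 3:
        yield base
        return
    yield from grow(base, labels[3:])
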