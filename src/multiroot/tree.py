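"""Core tree structures and operations.

Trees are stored as mutable nodes with parent/child links. An *unrooted*
binary tree on ``n`` leaves is represented with a degree-3 "top" node (the
usual basal trifurcation of unrooted Newick), so it has ``n - 2`` internal
nodes; a *rooted* binary tree has a degree-2 root and ``n - 1`` internal
nodes. Newick I/O is delegated to dendropy; everything else (rerooting,
restriction, clade and bipartition extraction) is implemented directly on
this node structure because downstream algorithms need cheap, explicit
control over edges and rootings.

Edges of an unrooted tree are identified by the leaf-label bipartition they
induce; the canonical identifier of an edge is the sorted tuple of labels on
the side *not* containing the lexicographically smallest leaf of the whole
tree. This identifier is stable under any traversal or rerooting, so score
tables indexed by it are joinable across runs.
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "NewickParseError",
    "TreeValidationError",
    "SpeciesMappingError",
    "SpeciesMapping",
    "parse_newick",
    "parse_newick_list",
    "read_newick_file",
    "write_newick_file",
    "enumerate_rootings",
    "restrict",
    "clades",
    "bipartitions",
    "unrooted_key",
    "random_binary_tree",
]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural precondition."""


class SpeciesMappingError(ValueError):
    """Raised when a gene-copy label cannot be resolved to a species."""


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None, children=None):
        self.label: str | None = label
        self.length: float | None = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        if children:
            for c in children:
                self.add_child(c)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {v.label for v in self.leaves()}

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Node({_subtree_newick(self)})"


class Tree:
    """A rooted or unrooted tree with optional branch lengths."""

    __slots__ = ("root", "rooted")

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # -- basic accessors -------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> set[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self) -> list[Node]:
        return [v for v in self.postorder() if not v.is_leaf]

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def is_binary(self) -> bool:
        if self.rooted:
            return all(len(v.children) == 2 for v in self.internal_nodes())
        if len(self.root.children) != 3:
            return self.n_leaves == 2 and len(self.root.children) == 2
        return all(
            len(v.children) == 2 for v in self.internal_nodes() if v is not self.root
        )

    # -- Newick ----------------------------------------------------------
    def newick(self) -> str:
        return _subtree_newick(self.root) + ";"

    def relabeled(self, fn: Callable[[str], str]) -> "Tree":
        out = self.copy()
        for leaf in out.leaves():
            leaf.label = fn(leaf.label)
        return out

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"Tree({kind}, {self.newick()})"


def _subtree_newick(node: Node) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        body = "(" + ",".join(_subtree_newick(c) for c in node.children) + ")"
        if node.label:
            body += node.label
    if node.length is not None:
        body += ":" + format(node.length, ".12g")
    return body


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_newick(text: str, rooted_hint: bool | None = None) -> Tree:
    """Parse one Newick string into a :class:`Tree`.

    A top-level trifurcation (or higher polytomy) yields an unrooted tree and
    a bifurcation a rooted tree, unless overridden by ``rooted_hint``.
    Polytomies below the top node are retained. Duplicate leaf labels raise
    :class:`TreeValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label=label, length=dnode.edge.length)
        node = Node(label=dnode.label, length=dnode.edge.length)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    labels = [v.label for v in root.leaves()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise NewickParseError("tree contains an unlabeled leaf")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"duplicate leaf labels: {dupes}")

    n_top = len(root.children)
    if rooted_hint is None:
        rooted = n_top == 2
    else:
        rooted = rooted_hint
    if not rooted and n_top == 2 and len(labels) > 2:
        # stored form of an unrooted tree uses a basal trifurcation
        root = _suppress_top(root)
    return Tree(root, rooted=rooted)


def _suppress_top(root: Node) -> Node:
    a, b = root.children
    internal = a if not a.is_leaf else b
    other = b if internal is a else a
    if internal.is_leaf:
        return root  # two-leaf tree, nothing to suppress
    other.length = _sum_lengths(other.length, internal.length)
    new_top = Node(label=internal.label)
    for c in internal.children:
        new_top.add_child(c)
    new_top.add_child(other)
    return new_top


def _sum_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def parse_newick_list(text: str, rooted_hint: bool | None = None) -> list[Tree]:
    """Parse a multi-tree string, one Newick per line (blank lines skipped)."""
    trees = []
    for line in io.StringIO(text):
        line = line.strip()
        if line:
            trees.append(parse_newick(line, rooted_hint=rooted_hint))
    return trees


def read_newick_file(path, rooted_hint: bool | None = None) -> list[Tree]:
    with open(path) as fh:
        return parse_newick_list(fh.read(), rooted_hint=rooted_hint)


def write_newick_file(path, trees: Iterable[Tree]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick() + "\n")


# ---------------------------------------------------------------------------
# Species mapping
# ---------------------------------------------------------------------------

class SpeciesMapping:
    """Resolve gene-copy leaf labels to species names.

    Either delimiter-based (species is the label prefix before the first
    occurrence of the delimiter; labels without the delimiter map to
    themselves, so species-labeled single-copy trees need no mapping file) or
    an explicit label -> species table.
    """

    def __init__(self, table: dict[str, str] | None = None, delimiter: str = "_"):
        self._table = table
        self._delim = delimiter

    @classmethod
    def delimiter(cls, delim: str = "_") -> "SpeciesMapping":
        return cls(delimiter=delim)

    @classmethod
    def from_table(cls, table: dict[str, str]) -> "SpeciesMapping":
        return cls(table=dict(table))

    @classmethod
    def from_file(cls, path) -> "SpeciesMapping":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise SpeciesMappingError(
                        f"mapping file line is not two-column TSV: {line!r}"
                    )
                table[parts[0]] = parts[1]
        return cls(table=table)

    def species_of(self, label: str) -> str:
        if self._table is not None:
            try:
                return self._table[label]
            except KeyError:
                raise SpeciesMappingError(
                    f"leaf label {label!r} has no species mapping"
                ) from None
        return label.split(self._delim, 1)[0]

    def species_set(self, labels: Iterable[str]) -> frozenset[str]:
        return frozenset(self.species_of(l) for l in labels)


DEFAULT_MAPPING = SpeciesMapping.delimiter("_")


# ---------------------------------------------------------------------------
# Edge identity and rooting enumeration
# ---------------------------------------------------------------------------

def edge_id_of_side(side: frozenset[str], all_labels: frozenset[str]) -> tuple[str, ...]:
    """Canonical id of an edge given the leaf set on one side of it."""
    smallest = min(all_labels)
    if smallest in side:
        side = all_labels - side
    return tuple(sorted(side))


def enumerate_rootings(tree: Tree) -> list[tuple[tuple[str, ...], Tree]]:
    """All ``2n - 3`` rootings of an unrooted binary tree, one per edge.

    Each rooting subdivides one edge with a new degree-2 root (branch lengths
    of the split edge are halved). Results are ordered by canonical edge id.
    """
    if tree.rooted:
        raise TreeValidationError("enumerate_rootings requires an unrooted tree")
    if not tree.is_binary():
        raise TreeValidationError("enumerate_rootings requires a binary tree")
    if tree.n_leaves < 3:
        raise TreeValidationError("need at least 3 leaves to enumerate rootings")
    all_labels = frozenset(tree.leaf_labels())
    out = []
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = frozenset(node.leaf_labels())
        eid = edge_id_of_side(side, all_labels)
        out.append((eid, _reroot_at(tree, node)))
    out.sort(key=lambda pair: pair[0])
    return out


def _half(x: float | None) -> float | None:
    return None if x is None else x / 2.0


def _reroot_at(tree: Tree, child: Node) -> Tree:
    """Rooted copy of ``tree`` with the root subdividing edge (parent, child)."""
    below = child.copy()
    below.length = _half(child.length)
    above = _build_away(child.parent, child)
    above.length = _half(child.length)
    root = Node(children=[below, above])
    return Tree(root, rooted=True)


def _build_away(node: Node, come_from: Node) -> Node:
    """Copy of the tree as seen from ``come_from`` looking into ``node``."""
    new = Node(label=node.label if node.is_leaf else None)
    parts: list[Node] = []
    for c in node.children:
        if c is not come_from:
            parts.append(c.copy())
    if node.parent is not None:
        up = _build_away(node.parent, node)
        up.length = node.length
        parts.append(up)
    if not parts:  # node is a leaf
        new.label = node.label
        return new
    if len(parts) == 1:  # degree-2 passthrough (top node of a rooted tree)
        part = parts[0]
        part.length = _sum_lengths(part.length, None)
        return part
    for p in parts:
        new.add_child(p)
    return new


# ---------------------------------------------------------------------------
# Restriction (induced subtree)
# ---------------------------------------------------------------------------

def restrict(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Induced subtree on ``taxa`` with degree-2 nodes suppressed.

    For a rooted input the result is rooted at the MRCA of ``taxa``; for an
    unrooted input the result is unrooted.
    """
    taxa = frozenset(taxa)
    present = tree.leaf_labels()
    if not taxa <= present:
        missing = sorted(taxa - present)
        raise TreeValidationError(f"taxa not in tree: {missing}")
    if len(taxa) < 2:
        raise TreeValidationError("restriction needs at least 2 taxa")

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in taxa:
                return Node(node.label, node.length)
            return None
        kept = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length = _sum_lengths(kept[0].length, node.length)
            return kept[0]
        new = Node(label=None, length=node.length)
        for k in kept:
            new.add_child(k)
        return new

    top = prune(tree.root)
    assert top is not None
    if tree.rooted:
        top.length = None
        top.parent = None
        return Tree(top, rooted=True)
    # unrooted: normalize to a basal trifurcation when possible
    if len(top.children) == 2 and len(taxa) > 2:
        top = _suppress_top(top)
    top.length = None
    top.parent = None
    return Tree(top, rooted=False)


# ---------------------------------------------------------------------------
# Clades and bipartitions
# ---------------------------------------------------------------------------

def clades(tree: Tree) -> set[frozenset[str]]:
    """Proper nontrivial clades of a rooted tree.

    Singletons and the full leaf set are excluded, so a rooted binary tree on
    ``n`` leaves has exactly ``n - 2`` clades.
    """
    if not tree.rooted:
        raise TreeValidationError("clades require a rooted tree")
    out: set[frozenset[str]] = set()
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset((node.label,))
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.children))
            sets[id(node)] = s
            if node is not tree.root and len(s) >= 2:
                out.add(s)
    return out


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the tree's unrooted topology.

    Each bipartition is represented by the canonical side (the side not
    containing the lexicographically smallest leaf).
    """
    all_labels = frozenset(tree.leaf_labels())
    n = len(all_labels)
    smallest = min(all_labels)
    out: set[frozenset[str]] = set()
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset((node.label,))
            continue
        s = frozenset().union(*(sets[id(c)] for c in node.children))
        sets[id(node)] = s
        if node is tree.root:
            continue
        side = s if smallest not in s else all_labels - s
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def unrooted_key(tree: Tree):
    """Hashable identifier of a tree's unrooted topology (labels + splits)."""
    return (frozenset(tree.leaf_labels()), frozenset(bipartitions(tree)))


# ---------------------------------------------------------------------------
# Random trees (used by tests and the simulator)
# ---------------------------------------------------------------------------

def random_binary_tree(labels: Sequence[str], rng, rooted: bool = True) -> Tree:
    """Uniform random-join binary tree topology over ``labels``."""
    labels = list(labels)
    if len(labels) < 2:
        raise TreeValidationError("need at least 2 labels")
    nodes = [Node(lbl) for lbl in labels]
    stop = 3 if (not rooted and len(labels) >= 3) else 1
    while len(nodes) > stop:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    if stop == 1:
        return Tree(nodes[0], rooted=True)
    if len(nodes) == 2:  # two labels, unrooted degenerate
        return Tree(Node(children=nodes), rooted=False)
    return Tree(Node(children=nodes), rooted=False)
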