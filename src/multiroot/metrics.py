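"""Tree-comparison metrics for rooting evaluation.

Robinson--Foulds (RF) on unrooted topologies, the normalized clade distance
(nCD) on rooted topologies, and the root distance. nCD is the rooted analogue
of RF:

    nCD(R*, R) = |Clades(R*) XOR Clades(R)| / (2n - 4)

with clades taken as the proper nontrivial clades (singletons and the full
leaf set excluded), so nCD lies in [0, 1] exactly. When the two rooted trees
share the same unrooted topology the clade symmetric difference equals twice
the root distance (the number of edges between the two root positions on the
shared unrooted topology), and :func:`ncd` asserts that relation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .tree import Tree, TreeValidationError, bipartitions, clades, enumerate_rootings

__all__ = [
    "RootingErrorReport",
    "rf_distance",
    "normalized_rf",
    "ncd",
    "root_distance",
    "evaluate_rooting",
    "expected_random_rooting_ncd",
    "unroot",
]


@dataclass
class RootingErrorReport:
    ncd: float
    n: int
    clade_diff: int
    root_distance: int | None
    same_unrooted: bool
    binary: bool = True


def _check_leafsets(a: Tree, b: Tree, min_n: int) -> int:
    la, lb = a.leaf_labels(), b.leaf_labels()
    if la != lb:
        raise TreeValidationError(
            f"leaf sets differ: only in first={sorted(la - lb)}, "
            f"only in second={sorted(lb - la)}"
        )
    n = len(la)
    if n < min_n:
        raise TreeValidationError(f"need at least {min_n} leaves, got {n}")
    return n


def rf_distance(a: Tree, b: Tree) -> int:
    """RF distance = size of the symmetric difference of nontrivial splits."""
    _check_leafsets(a, b, 4)
    return len(bipartitions(a) ^ bipartitions(b))


def normalized_rf(a: Tree, b: Tree) -> float:
    """RF normalized by 2(n-3), the maximum for binary trees."""
    n = _check_leafsets(a, b, 4)
    return rf_distance(a, b) / (2 * (n - 3))


# ---------------------------------------------------------------------------
# Root distance on a shared unrooted topology
# ---------------------------------------------------------------------------

def _root_edge_side(tree: Tree) -> frozenset[str]:
    """Canonical side of the edge on which a rooted tree's root sits."""
    all_labels = frozenset(tree.leaf_labels())
    smallest = min(all_labels)
    side = frozenset(tree.root.children[0].leaf_labels())
    return side if smallest not in side else all_labels - side


def _edge_graph(tree: Tree) -> dict[frozenset[str], set[frozenset[str]]]:
    """Adjacency between unrooted edges (edges sharing an endpoint)."""
    all_labels = frozenset(tree.leaf_labels())
    smallest = min(all_labels)

    def canon(side):
        return side if smallest not in side else all_labels - side

    below: dict[int, frozenset[str]] = {}
    for v in tree.postorder():
        if v.is_leaf:
            below[id(v)] = frozenset((v.label,))
        else:
            below[id(v)] = frozenset().union(*(below[id(c)] for c in v.children))

    root = tree.root
    merged_root_edge = tree.rooted and len(root.children) == 2
    # vertex -> incident edge ids
    incident: dict[int, set[frozenset[str]]] = {}

    def add(vertex: int, eid: frozenset[str]):
        incident.setdefault(vertex, set()).add(eid)

    for v in tree.postorder():
        if v is root:
            continue
        p = v.parent
        if merged_root_edge and p is root:
            continue  # handled below as a single merged edge
        eid = canon(below[id(v)])
        add(id(v), eid)
        add(id(p), eid)
    if merged_root_edge:
        c1, c2 = root.children
        eid = canon(below[id(c1)])
        add(id(c1), eid)
        add(id(c2), eid)

    adj: dict[frozenset[str], set[frozenset[str]]] = {}
    for edges in incident.values():
        for e in edges:
            adj.setdefault(e, set()).update(edges - {e})
    return adj


def root_distance(r_true: Tree, r_est: Tree) -> int:
    """Number of edges between the two root positions on the shared topology."""
    adj = _edge_graph(r_true)
    start = _root_edge_side(r_true)
    goal = _root_edge_side(r_est)
    if goal not in adj:
        raise TreeValidationError("root edge of estimate not found in true topology")
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        e, d = queue.popleft()
        for nb in adj[e]:
            if nb == goal:
                return d + 1
            if nb not in seen:
                seen.add(nb)
                queue.append((nb, d + 1))
    raise TreeValidationError("edge graph is disconnected")  # pragma: no cover


# ---------------------------------------------------------------------------
# nCD
# ---------------------------------------------------------------------------

def ncd(r_true: Tree, r_est: Tree) -> RootingErrorReport:
    """Normalized clade distance between two rooted trees on the same taxa."""
    n = _check_leafsets(r_true, r_est, 3)
    if not (r_true.rooted and r_est.rooted):
        raise TreeValidationError("ncd requires rooted trees")
    ca, cb = clades(r_true), clades(r_est)
    diff = len(ca ^ cb)
    value = diff / (2 * n - 4)
    binary = r_true.is_binary() and r_est.is_binary()
    same_unrooted = bipartitions(r_true) == bipartitions(r_est)
    rd: int | None = None
    if same_unrooted and binary:
        rd = root_distance(r_true, r_est)
        assert diff == 2 * rd, "clade distance must equal twice the root distance"
    return RootingErrorReport(
        ncd=value,
        n=n,
        clade_diff=diff,
        root_distance=rd,
        same_unrooted=same_unrooted,
        binary=binary,
    )


def expected_random_rooting_ncd(r_true: Tree) -> float:
    """Mean nCD over all 2n-3 rootings of the true tree's unrooted topology.

    This is the expected error of rooting by choosing an edge uniformly at
    random, the natural uninformed baseline.
    """
    unrooted = unroot(r_true)
    vals = [ncd(r_true, rooted).ncd for _, rooted in enumerate_rootings(unrooted)]
    return sum(vals) / len(vals)


def unroot(tree: Tree) -> Tree:
    """Unrooted copy of a tree (suppresses a degree-2 root)."""
    if not tree.rooted:
        return tree.copy()
    from .tree import _suppress_top

    root = tree.root.copy()
    if len(root.children) == 2 and tree.n_leaves > 2:
        root = _suppress_top(root)
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# Score-table evaluation
# ---------------------------------------------------------------------------

@dataclass
class RankCurvePoint:
    rank: int
    edge_id: tuple[str, ...]
    ncd: float
    root_distance: int | None


def evaluate_rooting(table, r_true: Tree):
    """Evaluate a rooting score table against the true rooted tree.

    Returns ``(report, curve)`` where ``report`` is the
    :class:`RootingErrorReport` of the rank-1 rooting and ``curve`` lists the
    nCD of every ranked rooting (a diagnostic of how well the score orders
    the candidate root positions).
    """
    rooted_by_edge = {eid: t for eid, t in enumerate_rootings(table.species_tree)}
    curve = []
    report = None
    for row in sorted(table.rows, key=lambda r: r.rank):
        cand = rooted_by_edge[row.edge_id]
        rep = ncd(r_true, cand)
        curve.append(
            RankCurvePoint(
                rank=row.rank, edge_id=row.edge_id, ncd=rep.ncd,
                root_distance=rep.root_distance,
            )
        )
        if row.rank == 1:
            report = rep
    return report, curve
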