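"""Five-taxon theory for species-tree rooting under the coalescent.

An unrooted binary tree on five taxa has 15 possible topologies and 7
possible rootings, for 105 rooted topologies falling into three unlabeled
shapes (caterpillar, balanced, pseudo-caterpillar). Under the multispecies
coalescent (MSC), the probability vector of the 15 unrooted gene-tree
topologies generated within a *rooted* 5-taxon species tree satisfies a set
of equalities and strict inequalities that depend on the rooted topology but
not on its branch lengths; those order structures are sufficient to identify
the rooted tree from unrooted gene-tree frequencies, and they are what makes
rooting from unrooted gene trees possible at all.

This module provides:

* a canonical catalog of the 15/7/105 topologies with index maps,
* a vectorized Monte-Carlo MSC oracle for quintet topology probabilities,
* empirical derivation of the per-rooted-topology order structure from the
  oracle (pairs whose verdict is not stable across branch-length draws are
  omitted, never guessed), with persistence to a small TSV,
* the rooting cost: an L1 penalty on violated equalities and orderings,
  which is zero exactly on distributions consistent with the rooted tree.

Only the three canonical shape structures are stored; the structure of any
of the 105 rooted topologies is obtained by relabeling, which is exact
because the MSC probability vector is equivariant under taxon permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .tree import Tree, TreeValidationError, clades, parse_newick

__all__ = [
    "QuintetCatalog",
    "QuintetDistribution",
    "OrderStructure",
    "SHAPES",
    "classify_shape",
    "msc_quintet_probs",
    "msc_quintet_counts",
    "derive_order_structure",
    "build_canonical_structures",
    "rooting_cost",
    "write_structures",
    "load_structures",
    "load_default_structures",
]

SHAPES = ("caterpillar", "balanced", "pseudo_caterpillar")

# canonical labeled tree of each shape, on positions 0..4
_SHAPE_NEWICK = {
    "caterpillar": "((((p0,p1),p2),p3),p4);",
    "balanced": "(((p0,p1),p2),(p3,p4));",
    "pseudo_caterpillar": "(((p0,p1),(p2,p3)),p4);",
}

_FULL = 31  # bitmask of all five positions


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _canon_split(mask: int) -> int:
    """Canonical side of a 2|3 split: the side not containing position 0."""
    return mask ^ _FULL if mask & 1 else mask


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

def _enumerate_unrooted() -> list[tuple[frozenset[int], frozenset[int]]]:
    """The 15 unrooted 5-leaf topologies as unordered pairs of disjoint cherries.

    A topology is determined by its two cherries {a,b}, {c,d} (the remaining
    taxon sits on the central path). Ordering is lexicographic on the sorted
    cherry pair, which is a canonical Newick ordering over positions.
    """
    seen = set()
    out = []
    for a, b in itertools.combinations(range(5), 2):
        rest = [x for x in range(5) if x not in (a, b)]
        for c, d in itertools.combinations(rest, 2):
            key = frozenset((frozenset((a, b)), frozenset((c, d))))
            if key in seen:
                continue
            seen.add(key)
    ordered = sorted(
        (tuple(sorted(tuple(sorted(ch)) for ch in key)) for key in seen)
    )
    for ch1, ch2 in ordered:
        out.append((frozenset(ch1), frozenset(ch2)))
    return out


_UNROOTED = _enumerate_unrooted()
assert len(_UNROOTED) == 15

# split-pair -> topology index lookup (splits encoded as canonical masks)
_SPLIT_PAIR_INDEX: dict[tuple[int, int], int] = {}
for _i, (_ch1, _ch2) in enumerate(_UNROOTED):
    _m1 = _canon_split(sum(1 << x for x in _ch1))
    _m2 = _canon_split(sum(1 << x for x in _ch2))
    _SPLIT_PAIR_INDEX[(min(_m1, _m2), max(_m1, _m2))] = _i

# dense lookup used by the vectorized simulator
_PAIR_LOOKUP = np.full(32 * 32, -1, dtype=np.int64)
for (_a, _b), _i in _SPLIT_PAIR_INDEX.items():
    _PAIR_LOOKUP[_a * 32 + _b] = _i


def _unrooted_newick(index: int, labels: list[str]) -> str:
    (a, b), (c, d) = (sorted(ch) for ch in _UNROOTED[index])
    mid = next(x for x in range(5) if x not in {a, b, c, d})
    L = labels
    return f"(({L[a]},{L[b]}),{L[mid]},({L[c]},{L[d]}));"


def classify_shape(tree: Tree) -> str:
    """Shape class of a rooted binary 5-taxon tree.

    Classification is by unlabeled-shape isomorphism; the multiset of proper
    clade sizes separates the three shapes exactly: caterpillar {2,3,4},
    balanced {2,2,3}, pseudo-caterpillar {2,2,4}.
    """
    if not tree.rooted:
        raise TreeValidationError("classify_shape requires a rooted tree")
    if tree.n_leaves != 5 or not tree.is_binary():
        raise TreeValidationError("classify_shape requires a binary 5-leaf tree")
    sizes = tuple(sorted(len(c) for c in clades(tree)))
    return {(2, 3, 4): "caterpillar", (2, 2, 3): "balanced",
            (2, 2, 4): "pseudo_caterpillar"}[sizes]


# ---------------------------------------------------------------------------
# Order structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderStructure:
    """Equalities and strict orderings among the 15 topology probabilities.

    ``eq_pairs`` holds unordered pairs (i, j), i < j, whose probabilities are
    equal for every branch length of the rooted topology; ``gt_pairs`` holds
    ordered pairs (i, j) with p_i > p_j for every branch length. Pairs whose
    verdict was unstable during derivation are counted in ``n_omitted`` and
    appear in neither set.
    """

    eq_pairs: frozenset[tuple[int, int]]
    gt_pairs: frozenset[tuple[int, int]]
    n_omitted: int = 0

    def permuted(self, topo_perm: dict[int, int]) -> "OrderStructure":
        eq = frozenset(
            tuple(sorted((topo_perm[i], topo_perm[j]))) for i, j in self.eq_pairs
        )
        gt = frozenset((topo_perm[i], topo_perm[j]) for i, j in self.gt_pairs)
        return OrderStructure(eq, gt, self.n_omitted)


@dataclass
class QuintetDistribution:
    """Empirical frequencies of the 15 unrooted topologies for one quintet."""

    freqs: np.ndarray  # shape (15,), sums to 1 when support > 0
    support: int  # number of gene trees that induced a resolved quintet

    @property
    def informative(self) -> bool:
        return self.support > 0


def rooting_cost(structure: OrderStructure, dist: QuintetDistribution) -> float:
    """Penalty of a topology distribution against a rooted tree's structure.

    cost = sum over equality pairs of |u_i - u_j|
         + sum over order pairs (i, j) of max(0, u_j - u_i)

    Zero exactly when every equality holds and no ordering is violated.
    """
    if isinstance(dist, QuintetDistribution):
        if not dist.informative:
            raise ValueError("cost of an uninformative (support 0) distribution")
        u = dist.freqs
    else:
        u = np.asarray(dist, dtype=float)
    cost = 0.0
    for i, j in structure.eq_pairs:
        cost += abs(u[i] - u[j])
    for i, j in structure.gt_pairs:
        d = u[j] - u[i]
        if d > 0:
            cost += d
    return float(cost)


# ---------------------------------------------------------------------------
# Vectorized Monte-Carlo MSC oracle
# ---------------------------------------------------------------------------

# pair-selection tables: for k lineages, _PAIR_I[k][r], _PAIR_J[k][r]
_PAIR_I = np.zeros((6, 10), dtype=np.int64)
_PAIR_J = np.zeros((6, 10), dtype=np.int64)
for _k in range(2, 6):
    for _r, (_i, _j) in enumerate(itertools.combinations(range(_k), 2)):
        _PAIR_I[_k, _r] = _i
        _PAIR_J[_k, _r] = _j


def _compile_tree(tree: Tree, labels: list[str]):
    """Post-order plan of internal nodes: (children specs, branch length)."""
    pos = {lbl: i for i, lbl in enumerate(labels)}
    plan = []
    index_of = {}
    for v in tree.postorder():
        if v.is_leaf:
            continue
        if len(v.children) != 2:
            raise TreeValidationError("MSC oracle requires a binary tree")
        kids = []
        for c in v.children:
            if c.is_leaf:
                kids.append(("leaf", pos[c.label]))
            else:
                kids.append(("node", index_of[id(c)]))
        length = np.inf if v is tree.root else (v.length or 0.0)
        if length < 0:
            raise TreeValidationError("negative branch length")
        index_of[id(v)] = len(plan)
        plan.append((kids, float(length)))
    return plan


def _simulate_topologies(tree: Tree, labels: list[str], n: int, rng) -> np.ndarray:
    """Topology index (0..14) of ``n`` MSC gene trees within ``tree``."""
    plan = _compile_tree(tree, labels)
    # lineage masks per internal node: (n, k) arrays, plus surviving counts
    store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    clade_masks = np.zeros((n, 4), dtype=np.int64)
    clade_count = np.zeros(n, dtype=np.int64)
    rows = np.arange(n)

    for vi, (kids, length) in enumerate(plan):
        cols = []
        counts = np.zeros(n, dtype=np.int64)
        for kind, ref in kids:
            if kind == "leaf":
                cols.append(np.full((n, 1), 1 << ref, dtype=np.int64))
                counts += 1
            else:
                lin, cnt = store.pop(ref)
                cols.append(lin)
                counts += cnt
        width = sum(c.shape[1] for c in cols)
        L = np.zeros((n, width), dtype=np.int64)
        # pack children lineages contiguously per sample
        off = np.zeros(n, dtype=np.int64)
        for c_arr in cols:
            w = c_arr.shape[1]
            valid = c_arr != 0
            for col in range(w):
                has = valid[:, col]
                L[rows[has], off[has]] = c_arr[has, col]
                off[has] += 1
        k = counts.copy()
        time_left = np.full(n, length)
        while True:
            active = k >= 2
            if not active.any():
                break
            rate = k * (k - 1) / 2.0
            dt = rng.exponential(1.0, n) / np.maximum(rate, 1.0)
            time_left = time_left - dt
            merge = active & (time_left > 0)
            if not merge.any():
                break
            npairs = (k * (k - 1)) // 2
            r = np.minimum(
                (rng.random(n) * npairs).astype(np.int64), np.maximum(npairs - 1, 0)
            )
            i_idx = _PAIR_I[k, r]
            j_idx = _PAIR_J[k, r]
            sel = np.flatnonzero(merge)
            a = L[sel, i_idx[sel]]
            b = L[sel, j_idx[sel]]
            merged = a | b
            clade_masks[sel, clade_count[sel]] = merged
            clade_count[sel] += 1
            L[sel, i_idx[sel]] = merged
            L[sel, j_idx[sel]] = L[sel, k[sel] - 1]
            L[sel, k[sel] - 1] = 0
            k[sel] -= 1
        store[vi] = (L, k)

    assert (clade_count == 4).all()
    # canonical nontrivial splits from clades of size 2 or 3
    pc = np.array([_popcount(m) for m in range(32)], dtype=np.int64)
    sizes = pc[clade_masks]
    canon = np.where(clade_masks & 1, clade_masks ^ _FULL, clade_masks)
    canon = np.where((sizes >= 2) & (sizes <= 3), canon, 0)
    srt = np.sort(canon, axis=1)  # ascending; zeros first
    x, y, z = srt[:, 3], srt[:, 2], srt[:, 1]
    second = np.where(y != x, y, z)
    lo = np.minimum(x, second)
    hi = np.maximum(x, second)
    idx = _PAIR_LOOKUP[lo * 32 + hi]
    assert (idx >= 0).all()
    return idx


def msc_quintet_counts(
    tree: Tree, n_samples: int, seed: int, labels: list[str] | None = None
) -> np.ndarray:
    """Counts over the 15 topologies of MSC gene trees simulated in ``tree``.

    Branch lengths of internal edges are in coalescent units; pendant edges
    carry single lineages and do not matter; lineages coalesce freely above
    the root.
    """
    if labels is None:
        labels = sorted(tree.leaf_labels())
    rng = np.random.default_rng(seed)
    idx = _simulate_topologies(tree, labels, int(n_samples), rng)
    return np.bincount(idx, minlength=15)


def msc_quintet_probs(
    tree: Tree, n_samples: int, seed: int, labels: list[str] | None = None
) -> np.ndarray:
    """Monte-Carlo estimate of the 15 topology probabilities under the MSC."""
    counts = msc_quintet_counts(tree, n_samples, seed, labels)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Structure derivation
# ---------------------------------------------------------------------------

DERIVATION_RANGE = (0.05, 2.0)  # coalescent units, strong to weak ILS
_SE_EQ = 4.0  # equality tolerance, in SEs of the estimated difference
_SE_STRICT = 6.0  # strictness threshold for detecting a generic ordering


def derive_order_structure(
    tree: Tree,
    n_draws: int = 200,
    n_samples: int = 100_000,
    seed: int = 0,
    draw_range: tuple[float, float] = DERIVATION_RANGE,
) -> OrderStructure:
    """Empirically derive the order structure of one rooted 5-taxon topology.

    For each of ``n_draws`` random branch-length assignments (internal edges
    uniform on ``draw_range`` coalescent units), topology probabilities are
    estimated with the Monte-Carlo oracle. A pair is an *equality* if the
    two components are statistically indistinguishable in every draw. A
    pair is an *ordering* (p_i above p_j) if the difference is never
    significantly negative in any draw and is significantly positive in at
    least one draw: the orderings that identify the root within a cherry
    are weak -- their margins vanish as ILS vanishes -- so demanding a
    strict margin everywhere would discard exactly the relations that make
    rooting identifiable. Pairs with inconsistent verdicts are omitted,
    never guessed.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    labels = sorted(tree.leaf_labels())
    work = tree.copy()
    internals = [
        v for v in work.postorder() if not v.is_leaf and v is not work.root
    ]
    rng = np.random.default_rng(seed)
    eq_ok = np.ones((15, 15), dtype=bool)
    never_reversed = np.ones((15, 15), dtype=bool)
    strict_somewhere = np.zeros((15, 15), dtype=bool)
    lo, hi = draw_range
    for _d in range(n_draws):
        for v in internals:
            v.length = float(rng.uniform(lo, hi))
        p = msc_quintet_probs(work, n_samples, int(rng.integers(2**31)), labels)
        se = np.sqrt(
            np.maximum(p[:, None] * (1 - p)[:, None] + p[None, :] * (1 - p)[None, :], 1e-12)
            / n_samples
        )
        diff = p[:, None] - p[None, :]
        eq_ok &= np.abs(diff) <= _SE_EQ * se
        never_reversed &= diff > -_SE_EQ * se
        strict_somewhere |= diff > _SE_STRICT * se
    gt_ok = never_reversed & strict_somewhere & ~eq_ok
    eq_pairs = {
        (i, j) for i in range(15) for j in range(i + 1, 15) if eq_ok[i, j]
    }
    gt_pairs = {
        (i, j) for i in range(15) for j in range(15) if i != j and gt_ok[i, j]
    }
    n_total = 15 * 14 // 2
    n_omitted = n_total - len(eq_pairs) - len(
        {tuple(sorted(p)) for p in gt_pairs}
    )
    return OrderStructure(frozenset(eq_pairs), frozenset(gt_pairs), n_omitted)


def _permute_topology_index(sigma: dict[int, int]) -> dict[int, int]:
    """Action of a position permutation on the 15 topology indices."""
    out = {}
    for i, (ch1, ch2) in enumerate(_UNROOTED):
        m1 = _canon_split(sum(1 << sigma[x] for x in ch1))
        m2 = _canon_split(sum(1 << sigma[x] for x in ch2))
        out[i] = _SPLIT_PAIR_INDEX[(min(m1, m2), max(m1, m2))]
    return out


def _rooted_id(tree: Tree, labels: list[str]) -> frozenset[frozenset[int]]:
    pos = {lbl: i for i, lbl in enumerate(labels)}
    return frozenset(
        frozenset(pos[l] for l in c) for c in clades(tree)
    )


def _apply_perm_to_id(rid, sigma):
    return frozenset(frozenset(sigma[x] for x in c) for c in rid)


def _shape_canonical_tree(shape: str) -> Tree:
    return parse_newick(_SHAPE_NEWICK[shape])


_P_LABELS = ["p0", "p1", "p2", "p3", "p4"]


def _shape_automorphisms(shape: str) -> list[dict[int, int]]:
    t = _shape_canonical_tree(shape)
    rid = _rooted_id(t, _P_LABELS)
    out = []
    for perm in itertools.permutations(range(5)):
        sigma = dict(enumerate(perm))
        if _apply_perm_to_id(rid, sigma) == rid:
            out.append(sigma)
    return out


def _symmetrize(structure: OrderStructure, shape: str) -> OrderStructure:
    """Close the structure under the shape's automorphisms, then close
    equalities transitively so equality is an equivalence relation."""
    autos = [_permute_topology_index(s) for s in _shape_automorphisms(shape)]
    eq = {
        (i, j)
        for (i, j) in structure.eq_pairs
        if all(tuple(sorted((a[i], a[j]))) in structure.eq_pairs for a in autos)
    }
    gt = {
        (i, j)
        for (i, j) in structure.gt_pairs
        if all((a[i], a[j]) in structure.gt_pairs for a in autos)
    }
    # transitive closure of equalities via union-find
    parent = list(range(15))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in eq:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    classes: dict[int, list[int]] = {}
    for x in range(15):
        classes.setdefault(find(x), []).append(x)
    closed_eq = set()
    for members in classes.values():
        for i, j in itertools.combinations(sorted(members), 2):
            closed_eq.add((i, j))
    # drop orderings that contradict an equality class
    gt = {(i, j) for (i, j) in gt if tuple(sorted((i, j))) not in closed_eq}
    n_total = 15 * 14 // 2
    n_omitted = n_total - len(closed_eq) - len({tuple(sorted(p)) for p in gt})
    return OrderStructure(frozenset(closed_eq), frozenset(gt), n_omitted)


def build_canonical_structures(
    n_samples: int = 1_000_000, n_draws: int = 200, seed: int = 1
) -> dict[str, OrderStructure]:
    """Derive, symmetrize and return the three canonical shape structures."""
    out = {}
    for si, shape in enumerate(SHAPES):
        t = _shape_canonical_tree(shape)
        raw = derive_order_structure(
            t, n_draws=n_draws, n_samples=n_samples, seed=seed + 7919 * si
        )
        out[shape] = _symmetrize(raw, shape)
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

STRUCTURE_FILE_VERSION = 1


def write_structures(path, structures: dict[str, OrderStructure], meta: str = ""):
    with open(path, "w") as fh:
        fh.write(f"# order-structures v{STRUCTURE_FILE_VERSION} {meta}\n")
        fh.write("shape\tkind\ti\tj\n")
        for shape in SHAPES:
            s = structures[shape]
            for i, j in sorted(s.eq_pairs):
                fh.write(f"{shape}\teq\t{i}\t{j}\n")
            for i, j in sorted(s.gt_pairs):
                fh.write(f"{shape}\tgt\t{i}\t{j}\n")


def load_structures(path_or_fh) -> dict[str, OrderStructure]:
    if hasattr(path_or_fh, "read"):
        lines = path_or_fh.read().splitlines()
    else:
        with open(path_or_fh) as fh:
            lines = fh.read().splitlines()
    eq: dict[str, set] = {s: set() for s in SHAPES}
    gt: dict[str, set] = {s: set() for s in SHAPES}
    for line in lines:
        if not line or line.startswith("#") or line.startswith("shape\t"):
            continue
        shape, kind, i, j = line.split("\t")
        (eq if kind == "eq" else gt)[shape].add((int(i), int(j)))
    out = {}
    for shape in SHAPES:
        n_total = 15 * 14 // 2
        n_omitted = n_total - len(eq[shape]) - len(
            {tuple(sorted(p)) for p in gt[shape]}
        )
        out[shape] = OrderStructure(
            frozenset(eq[shape]), frozenset(gt[shape]), n_omitted
        )
    return out


_DEFAULT_STRUCTURES: dict[str, OrderStructure] | None = None


def load_default_structures() -> dict[str, OrderStructure]:
    global _DEFAULT_STRUCTURES
    if _DEFAULT_STRUCTURES is None:
        ref = resources.files("multiroot").joinpath("data/order_structures.tsv")
        with ref.open() as fh:
            _DEFAULT_STRUCTURES = load_structures(fh)
    return _DEFAULT_STRUCTURES


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

class _PositionTables:
    """Position-coded rooting tables shared by all catalogs.

    Everything here is expressed over positions 0..4, so one instance serves
    every 5-taxon label set using a given structure dictionary.
    """

    def __init__(self, structures: dict[str, OrderStructure]):
        from .tree import enumerate_rootings as _enum

        self.rootings: list[list[frozenset]] = []
        self.rooted_info: dict[frozenset, dict] = {}
        shape_rids = {
            shape: _rooted_id(_shape_canonical_tree(shape), _P_LABELS)
            for shape in SHAPES
        }
        for ti in range(15):
            t = parse_newick(_unrooted_newick(ti, _P_LABELS))
            rids = []
            for _eid, rooted in _enum(t):
                rid = _rooted_id(rooted, _P_LABELS)
                rids.append(rid)
                if rid in self.rooted_info:
                    continue
                shape = classify_shape(rooted)
                sigma = self._find_relabeling(shape_rids[shape], rid)
                topo_perm = _permute_topology_index(sigma)
                structure = structures[shape].permuted(topo_perm)
                self.rooted_info[rid] = {
                    "shape": shape,
                    "sigma": sigma,
                    "structure": structure,
                    "unrooted_index": ti,
                }
            self.rootings.append(rids)
        assert len(self.rooted_info) == 105

    @staticmethod
    def _find_relabeling(canon_rid, rid) -> dict[int, int]:
        for perm in itertools.permutations(range(5)):
            sigma = dict(enumerate(perm))
            if _apply_perm_to_id(canon_rid, sigma) == rid:
                return sigma
        raise AssertionError("no relabeling found between same-shape trees")


# keyed by id(); the cache keeps a strong reference to each structures dict
# so ids cannot be recycled while the cache lives
_TABLES_CACHE: dict[int, tuple[dict, _PositionTables]] = {}


def _tables_for(structures: dict[str, OrderStructure]) -> _PositionTables:
    key = id(structures)
    if key not in _TABLES_CACHE:
        _TABLES_CACHE[key] = (structures, _PositionTables(structures))
    return _TABLES_CACHE[key][1]


class QuintetCatalog:
    """Canonical enumeration of quintet topologies for one 5-taxon label set.

    Topology indices refer to the canonical order of the 15 unrooted
    topologies over positions 0..4, where position i is the i-th label in
    sorted order. Rooted topologies are identified by their (position-coded)
    clade sets; each carries a shape, a relabeling from the shape's
    canonical tree, and its order structure. The heavy position-coded tables
    are built once per structure set and shared across label sets.
    """

    def __init__(self, labels, structures: dict[str, OrderStructure] | None = None):
        labels = sorted(labels)
        if len(labels) != 5 or len(set(labels)) != 5:
            raise TreeValidationError("catalog needs exactly 5 distinct labels")
        self.labels = list(labels)
        self._pos = {lbl: i for i, lbl in enumerate(self.labels)}
        if structures is None:
            structures = load_default_structures()
        tables = _tables_for(structures)
        self.rootings = tables.rootings
        self._rooted_info = tables.rooted_info
        self.unrooted_newicks = [
            _unrooted_newick(i, self.labels) for i in range(15)
        ]

    # -- index maps ------------------------------------------------------
    def topology_index(self, tree: Tree) -> int | None:
        """Index of a 5-leaf tree's unrooted topology; None if unresolved."""
        from .tree import bipartitions

        if tree.leaf_labels() != set(self.labels):
            raise TreeValidationError("tree labels do not match catalog labels")
        splits = bipartitions(tree)
        if len(splits) != 2:
            return None
        masks = sorted(
            _canon_split(sum(1 << self._pos[l] for l in s)) for s in splits
        )
        return _SPLIT_PAIR_INDEX.get((masks[0], masks[1]))

    def rooted_id(self, tree: Tree) -> frozenset:
        return _rooted_id(tree, self.labels)

    def shape_of(self, rid) -> str:
        return self._rooted_info[rid]["shape"]

    def structure_of(self, rid) -> OrderStructure:
        return self._rooted_info[rid]["structure"]

    def structure_for_tree(self, rooted_tree: Tree) -> OrderStructure:
        return self.structure_of(self.rooted_id(rooted_tree))

    def matching_index(self, rid) -> int:
        """Unrooted topology index matching a rooted topology."""
        return self._rooted_info[rid]["unrooted_index"]
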