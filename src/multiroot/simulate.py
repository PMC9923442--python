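"""Synthetic gene-family data: duplication/loss, coalescence, and noise.

The generator emulates, at desk scale, the standard two-stage model of gene
family evolution used to benchmark rooting methods:

1. a pure-birth (Yule) species tree on ``n_species`` tips, rescaled to a
   fixed height in time units;
2. per gene, a *locus tree* produced by a birth-death walk of gene lineages
   down the species tree (duplications copy a lineage in place, losses kill
   it; surviving copies at the tips become leaves ``SPECIES_copyindex``);
3. per gene, a *gene tree* produced by the multispecies coalescent run
   inside the locus tree, with time converted to coalescent units by
   ``ils_scale`` (coalescent units per time unit: a small multiplier means
   short coalescent branches, i.e. high ILS);
4. optionally, topological noise standing in for gene-tree estimation
   error: a calibrated number of random NNI moves per gene tree.

ILS level is summarized by AD, the mean normalized Robinson-Foulds distance
between each locus tree and its gene tree; estimation error by the mean
normalized RF between each gene tree and its perturbed copy. Duplication
and loss rates are quoted on the per-substitution scale used by standard
GDL simulators and converted to the internal time clock by ``rate_scale``,
so rate sweeps reproduce relative, not absolute, regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import normalized_rf, unroot
from .tree import Node, Tree, TreeValidationError

__all__ = [
    "SimConfig",
    "SimReplicate",
    "ILS_LOW_SCALE",
    "ILS_HIGH_SCALE",
    "GTEE_MODERATE_OPS",
    "simulate_species_tree",
    "simulate_locus_tree",
    "simulate_gene_tree",
    "perturb_gene_tree",
    "average_distance",
    "simulate_replicate",
    "calibrate_ils_scale",
    "calibrate_gtee_ops",
]

# coalescent-units-per-time presets calibrated once on the default
# 21-species, height-1.0 configuration (see docs/methods.md):
# ILS_LOW_SCALE gives AD ~= 0.20, ILS_HIGH_SCALE gives AD ~= 0.64,
# averaged over species-tree realizations (per-replicate AD varies with the
# drawn tree shape).
ILS_LOW_SCALE = 20.0
ILS_HIGH_SCALE = 2.4

# moderate gene-tree estimation error: NNI count per gene tree calibrated to
# a mean normalized RF of ~0.40 on 21-taxon trees.
GTEE_MODERATE_OPS = 11


@dataclass
class SimConfig:
    """Parameters of one synthetic replicate (defaults: the 21-species,
    1000-gene, moderate-duplication, high-ILS study condition)."""

    n_species: int = 21
    birth_rate: float = 1.0  # speciation rate of the Yule process, per time
    height: float = 1.0  # species tree height, time units
    dup_rate: float = 1e-12  # per-substitution-scale duplication rate
    loss_rate: float | None = None  # None -> equal to dup_rate
    rate_scale: float = 1e11  # converts per-substitution rates to per-time
    ils_scale: float = ILS_HIGH_SCALE  # coalescent units per time unit
    n_genes: int = 1000
    gtee_ops: int = 0  # random NNI moves per gene tree (0 = no noise)
    seed: int = 0
    skip_empty: bool = True  # drop all-extinct gene families (recorded)

    def __post_init__(self):
        if self.n_species < 5:
            raise TreeValidationError("n_species must be >= 5")
        if self.dup_rate < 0 or (self.loss_rate or 0) < 0:
            raise TreeValidationError("rates must be >= 0")
        if self.n_genes < 1:
            raise TreeValidationError("n_genes must be >= 1")
        if self.ils_scale <= 0:
            raise TreeValidationError("ils_scale must be > 0")

    @property
    def effective_dup_rate(self) -> float:
        return self.dup_rate * self.rate_scale

    @property
    def effective_loss_rate(self) -> float:
        lr = self.dup_rate if self.loss_rate is None else self.loss_rate
        return lr * self.rate_scale


@dataclass
class SimReplicate:
    species_tree: Tree  # true rooted species tree, ultrametric
    locus_trees: list[Tree]  # per-gene MUL-trees (GDL only)
    gene_trees: list[Tree]  # per-gene MSC gene trees (GDL + ILS)
    perturbed_gene_trees: list[Tree]  # with topological noise (GDL+ILS+GTEE)
    ad: float  # realized mean normalized RF(locus, gene)
    mgte: float  # realized mean normalized RF(gene, perturbed)
    n_all_extinct: int = 0
    n_dup_events: int = 0


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int, birth_rate: float = 1.0, height: float = 1.0, seed: int = 0,
    rng=None,
) -> Tree:
    """Yule tree conditioned on ``n_species`` tips, rescaled to ``height``.

    Ultrametric by construction: every root-to-tip path has length
    ``height``. Tip labels are S01, S02, ... in the order of creation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    root = Node()
    active: list[tuple[Node, float]] = [
        (root.add_child(Node()), 0.0),
        (root.add_child(Node()), 0.0),
    ]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, t0 = active.pop(i)
        if node is not root:
            node.length = t - t0
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t_end = t + rng.exponential(1.0 / (n_species * birth_rate))
    width = len(str(n_species))
    for i, (node, t0) in enumerate(active):
        node.label = f"S{i + 1:0{width}d}"
        node.length = t_end - t0
    tree = Tree(root, rooted=True)
    scale = height / t_end
    for v in tree.postorder():
        if v.length is not None:
            v.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Locus tree (gene duplication and loss)
# ---------------------------------------------------------------------------

def simulate_locus_tree(
    species_tree: Tree, dup_rate: float, loss_rate: float, seed: int = 0, rng=None,
) -> tuple[Tree | None, int]:
    """Birth-death walk of gene lineages down the species tree.

    Rates are per lineage per time unit. Starting from one lineage at the
    root, each lineage independently accrues duplications (the lineage is
    copied; both copies continue down the species tree from that point) and
    losses (the lineage terminates). Returns ``(locus_tree, n_dup_events)``;
    the tree is None when every lineage dies. Surviving copies are labeled
    ``species_copyindex``; internal node lengths are in time units and tips
    all reach the present (the walk preserves ultrametricity).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dup_events = [0]

    def draw(rate: float) -> float:
        return rng.exponential(1.0 / rate) if rate > 0 else np.inf

    def from_node(v: Node) -> Node | None:
        if v.is_leaf:
            return Node(label=v.label, length=0.0)
        kids = [along_branch(c, 0.0) for c in v.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return Node(children=kids, length=0.0)

    def along_branch(c: Node, pos: float) -> Node | None:
        L = c.length or 0.0
        t_dup = draw(dup_rate)
        t_loss = draw(loss_rate)
        t = min(t_dup, t_loss)
        if pos + t >= L:
            sub = from_node(c)
            if sub is None:
                return None
            sub.length = (sub.length or 0.0) + (L - pos)
            return sub
        if t_loss <= t_dup:
            return None
        dup_events[0] += 1
        left = along_branch(c, pos + t)
        right = along_branch(c, pos + t)
        if left is None and right is None:
            return None
        if left is None or right is None:
            surv = left if left is not None else right
            surv.length = (surv.length or 0.0) + t
            return surv
        return Node(children=[left, right], length=t)

    root = from_node(species_tree.root)
    if root is None:
        return None, dup_events[0]
    root.length = None
    # assign copy indices per species in a deterministic traversal order
    counters: dict[str, int] = {}
    for leaf in root.leaves():
        sp = leaf.label
        counters[sp] = counters.get(sp, 0) + 1
        leaf.label = f"{sp}_{counters[sp]}"
    return Tree(root, rooted=True), dup_events[0]


# ---------------------------------------------------------------------------
# Gene tree (multispecies coalescent within the locus tree)
# ---------------------------------------------------------------------------

def simulate_gene_tree(
    locus_tree: Tree, ils_scale: float, seed: int = 0, rng=None
) -> Tree:
    """Standard MSC inside the locus tree, one sample per locus-tree leaf.

    Branch lengths of the locus tree (time units) are converted to
    coalescent units via ``ils_scale``; lineages that reach the locus root
    coalesce freely above it. Leaf labels are preserved; output branch
    lengths are in coalescent units.
    """
    if ils_scale <= 0:
        raise TreeValidationError("ils_scale must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if locus_tree.n_leaves == 1:
        leaf = locus_tree.leaves()[0]
        return Tree(Node(label=leaf.label), rooted=True)

    # ages (coalescent units above the present) of each locus node's bottom
    depth: dict[int, float] = {id(locus_tree.root): 0.0}
    for v in locus_tree.preorder():
        if v is locus_tree.root:
            continue
        depth[id(v)] = depth[id(v.parent)] + (v.length or 0.0)
    H = max(depth[id(l)] for l in locus_tree.leaves())

    def age_of(v: Node) -> float:
        return (H - depth[id(v)]) * ils_scale

    def coalesce(lineages, start_age, end_age):
        age = start_age
        while len(lineages) > 1:
            k = len(lineages)
            age += rng.exponential(2.0 / (k * (k - 1)))
            if age >= end_age:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            b = lineages.pop(int(j))
            a = lineages.pop(int(i))
            for child, child_age in (a, b):
                child.length = age - child_age
            merged = Node(children=[a[0], b[0]])
            lineages.append((merged, age))
        return lineages

    def sim(v: Node):
        if v.is_leaf:
            lineages = [(Node(label=v.label), age_of(v))]
        else:
            lineages = []
            for c in v.children:
                lineages.extend(sim(c))
        top = np.inf if v is locus_tree.root else age_of(v) + (v.length or 0.0) * ils_scale
        return coalesce(lineages, age_of(v), top)

    (root, _age), = sim(locus_tree.root)
    root.length = None
    return Tree(root, rooted=True)


# ---------------------------------------------------------------------------
# Topological noise (gene tree estimation error proxy)
# ---------------------------------------------------------------------------

def perturb_gene_tree(tree: Tree, n_ops: int, seed: int = 0, rng=None) -> Tree:
    """Apply ``n_ops`` random nearest-neighbor-interchange moves.

    Each move picks a random internal edge (parent, child) and swaps one of
    the child's subtrees with the child's sibling. Trees with fewer than 4
    leaves are returned unchanged.
    """
    if n_ops < 0:
        raise TreeValidationError("n_ops must be >= 0")
    out = tree.copy()
    if tree.n_leaves < 4 or n_ops == 0:
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(n_ops):
        internal_edges = [
            v
            for v in out.postorder()
            if not v.is_leaf and v.parent is not None and len(v.parent.children) == 2
        ]
        if not internal_edges:
            break
        v = internal_edges[int(rng.integers(len(internal_edges)))]
        u = v.parent
        sibling = u.children[0] if u.children[1] is v else u.children[1]
        c = v.children[int(rng.integers(len(v.children)))]
        # swap c and sibling
        ci = v.children.index(c)
        si = u.children.index(sibling)
        v.children[ci] = sibling
        sibling.parent = v
        u.children[si] = c
        c.parent = u
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def average_distance(locus_trees, gene_trees) -> float:
    """AD: mean normalized RF between paired locus and gene trees.

    Leaves are compared as gene-copy labels. Pairs with fewer than 4 leaves
    are skipped; a leaf-set mismatch raises an error naming the gene.
    """
    if len(locus_trees) != len(gene_trees):
        raise TreeValidationError("locus/gene tree lists differ in length")
    vals = []
    for gi, (lt, gt) in enumerate(zip(locus_trees, gene_trees)):
        if lt.leaf_labels() != gt.leaf_labels():
            raise TreeValidationError(f"gene {gi}: leaf sets differ")
        if lt.n_leaves < 4:
            continue
        vals.append(normalized_rf(lt, gt))
    return float(np.mean(vals)) if vals else 0.0


def simulate_replicate(cfg: SimConfig) -> SimReplicate:
    """One full synthetic replicate under ``cfg`` (deterministic given seed)."""
    seq = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in seq.spawn(4)]
    sp = simulate_species_tree(
        cfg.n_species, cfg.birth_rate, cfg.height, rng=rngs[0]
    )
    locus_trees: list[Tree] = []
    gene_trees: list[Tree] = []
    perturbed: list[Tree] = []
    n_extinct = 0
    n_dups = 0
    while len(locus_trees) < cfg.n_genes:
        lt, nd = simulate_locus_tree(
            sp, cfg.effective_dup_rate, cfg.effective_loss_rate, rng=rngs[1]
        )
        if lt is None:
            n_extinct += 1
            if not cfg.skip_empty:
                raise TreeValidationError("all-extinct gene family")
            continue
        n_dups += nd
        gt = simulate_gene_tree(lt, cfg.ils_scale, rng=rngs[2])
        locus_trees.append(lt)
        gene_trees.append(gt)
        perturbed.append(perturb_gene_tree(gt, cfg.gtee_ops, rng=rngs[3]))
    ad = average_distance(locus_trees, gene_trees)
    mgte = average_distance(gene_trees, perturbed) if cfg.gtee_ops else 0.0
    return SimReplicate(
        species_tree=sp,
        locus_trees=locus_trees,
        gene_trees=gene_trees,
        perturbed_gene_trees=perturbed,
        ad=ad,
        mgte=mgte,
        n_all_extinct=n_extinct,
        n_dup_events=n_dups,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_ils_scale(
    target_ad: float,
    cfg: SimConfig | None = None,
    n_genes: int = 200,
    tol: float = 0.02,
    max_iter: int = 18,
) -> float:
    """Bisection for the ``ils_scale`` that realizes a target AD.

    AD is monotonically decreasing in ``ils_scale`` (more coalescent units
    per time unit means less ILS), so a log-scale bisection converges.
    """
    if cfg is None:
        cfg = SimConfig()
    lo, hi = 0.05, 200.0

    def ad_at(scale: float) -> float:
        c = replace(cfg, ils_scale=scale, n_genes=n_genes, gtee_ops=0)
        return simulate_replicate(c).ad

    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        ad = ad_at(mid)
        if abs(ad - target_ad) <= tol:
            return mid
        if ad > target_ad:
            lo = mid  # too much ILS: increase scale
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def calibrate_gtee_ops(
    target_nrf: float, trees: list[Tree], seed: int = 0, max_ops: int = 60
) -> int:
    """Smallest NNI count whose mean normalized RF reaches ``target_nrf``."""
    rng = np.random.default_rng(seed)
    for ops in range(1, max_ops + 1):
        vals = [
            normalized_rf(t, perturb_gene_tree(t, ops, rng=rng))
            for t in trees
            if t.n_leaves >= 4
        ]
        if vals and float(np.mean(vals)) >= target_nrf:
            return ops
    return max_ops
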