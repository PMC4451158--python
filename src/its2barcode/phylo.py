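"""Neighbor-joining trees, column bootstrap, monophyly tests and Newick I/O.

Neighbor joining follows the classic agglomerative recipe: at each step the
pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j is joined, with branch
lengths from the rate-corrected split formulas. Ties are broken by the
lexicographically smallest pair of cluster representatives so trees are
bit-reproducible. The output is unrooted (a basal trifurcation); negative
branch-length estimates are clamped to zero by default and the deficit
logged, the convention of mainstream distance-tree software.

Bootstrap support resamples alignment columns with replacement, rebuilds
K2P + NJ per replicate, and reports the recovery percentage of each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .distance import DistanceMatrix, _count_encoded, encode_row, k2p_distance
from .errors import ComputationError, SaturatedDistanceError, ValidationError

log = logging.getLogger(__name__)


class TreeNode:
    """Node of an (un)rooted phylogeny; leaves carry a ``name``."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = list(children) if children else []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """A tree with branch lengths and optional bootstrap supports."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(n):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def _leafsets(self) -> list[tuple[TreeNode, frozenset[str]]]:
        out = []

        def walk(n) -> frozenset:
            if n.is_leaf:
                s = frozenset([n.name])
            else:
                s = frozenset().union(*(walk(c) for c in n.children))
            out.append((n, s))
            return s

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions, canonicalized to the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}
        for node, side in self._leafsets():
            if node is self.root:
                continue
            canon = all_leaves - side if ref in side else side
            if 2 <= len(canon) <= len(all_leaves) - 2:
                out[canon] = node
        return out

    def to_newick(self, precision: int = 6, include_support: bool = True) -> str:
        def fmt_len(x):
            return "" if x is None else f":{x:.{precision}f}"

        def walk(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}{fmt_len(n.length)}"
            inner = ",".join(walk(c) for c in n.children)
            label = ""
            if include_support and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}{fmt_len(n.length)}"

        return walk(self.root) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Unrooted NJ tree from a distance matrix (>= 3 taxa, finite entries)."""
    n = len(dm)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValidationError("distance matrix contains non-finite entries")

    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    reps: list[str] = list(dm.ids)
    clamped_total = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped_total
        if clamp_negative and x < 0:
            clamped_total += -x
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        # Zero-distance taxa are indistinguishable: any resolution separating
        # them is a tie-break artifact, so they are agglomerated first. The
        # Q-criterion then acts on the reduced problem (identical behavior to
        # plain NJ whenever no off-diagonal zero exists).
        zero = np.argwhere((D == 0.0) & ~np.eye(r, dtype=bool))
        if len(zero):
            cand = {(min(i, j), max(i, j)) for i, j in zero}
        else:
            Q = (r - 2) * D - R[:, None] - R[None, :]
            Q = np.minimum(Q, Q.T)  # exact symmetry despite float summation
            np.fill_diagonal(Q, np.inf)
            qmin = Q.min()
            cand = {(min(i, j), max(i, j)) for i, j in np.argwhere(Q == qmin)}
        best = min(cand, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))
        i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = clamp(li), clamp(lj)
        a, b = sorted((i, j), key=lambda k: reps[k])
        nodes[a].length, nodes[b].length = (li, lj) if a == i else (lj, li)
        parent = TreeNode(children=[nodes[a], nodes[b]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    (x, y, z) = range(3)
    lx = clamp(0.5 * (D[x, y] + D[x, z] - D[y, z]))
    ly = clamp(0.5 * (D[x, y] + D[y, z] - D[x, z]))
    lz = clamp(0.5 * (D[x, z] + D[y, z] - D[x, y]))
    for node, ln in zip(nodes, (lx, ly, lz)):
        node.length = ln
    order = sorted(range(3), key=lambda k: reps[k])
    root = TreeNode(children=[nodes[k] for k in order])
    if clamped_total > 0:
        log.info("clamped negative NJ branch lengths; total deficit %.6g", clamped_total)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0
    display_threshold: float = 50.0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


def _nj_bipartitions_encoded(enc_uniq, rep_of, ids) -> set[frozenset[str]]:
    """K2P + NJ + bipartition set from encoded unique rows (one replicate)."""
    k = len(enc_uniq)
    du = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            du[a, b] = du[b, a] = k2p_distance(_count_encoded(enc_uniq[a], enc_uniq[b]))
    full = du[np.ix_(rep_of, rep_of)]
    np.fill_diagonal(full, 0.0)
    tree = neighbor_joining(DistanceMatrix(tuple(ids), full))
    return set(tree.bipartitions())


def bootstrap_support(msa, cfg: BootstrapConfig = BootstrapConfig()) -> PhyloTree:
    """NJ tree of the alignment with column-bootstrap supports (percent).

    Supports are attached to internal nodes for every bipartition of the
    full-data tree; values below ``cfg.display_threshold`` are retained on
    the tree but suppressed by the rendering helpers. Replicates whose
    resampled distances saturate are dropped (still counted in the
    denominator) and logged.
    """
    ids = list(msa.rows)
    if len(ids) < 4:
        raise ValidationError("need >= 4 rows for informative supports")
    rows = [msa.rows[i] for i in ids]
    group_of: dict[str, int] = {}
    uniq_rows: list[str] = []
    rep_of = np.empty(len(rows), dtype=int)
    for idx, row in enumerate(rows):
        g = group_of.setdefault(row, len(uniq_rows))
        if g == len(uniq_rows):
            uniq_rows.append(row)
        rep_of[idx] = g
    enc = np.stack([encode_row(r) for r in uniq_rows])
    n_cols = enc.shape[1]

    from .distance import distance_matrix  # avoid import at module load order issues

    tree = neighbor_joining(distance_matrix(msa))
    orig = tree.bipartitions()
    counts = {bip: 0 for bip in orig}

    rng = np.random.default_rng(cfg.seed)
    dropped = 0
    for _ in range(cfg.replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            bips = _nj_bipartitions_encoded(list(enc[:, cols]), rep_of, ids)
        except (SaturatedDistanceError, ComputationError):
            dropped += 1
            continue
        for bip in counts:
            if bip in bips:
                counts[bip] += 1
    if dropped:
        log.warning("%d/%d bootstrap replicates dropped (saturation)", dropped, cfg.replicates)
    for bip, node in orig.items():
        node.support = 100.0 * counts[bip] / cfg.replicates
    return tree


def species_clade_supports(tree: PhyloTree, labels) -> dict[str, float | None]:
    """Bootstrap support of each species' sample bipartition.

    ``None`` when the species is a singleton (trivial split) or its samples
    are not monophyletic on the tree.
    """
    bips = tree.bipartitions()
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: dict[str, float | None] = {}
    for sp in dict.fromkeys(labels[i] for i in tree.leaf_names()):
        target = frozenset(i for i in all_leaves if labels[i] == sp)
        canon = all_leaves - target if ref in target else target
        node = bips.get(canon)
        out[sp] = node.support if node is not None else None
    return out


# ---------------------------------------------------------------------------
# Monophyly


def is_monophyletic(tree: PhyloTree, labels, species: str) -> bool:
    """True iff some edge separates exactly this species' leaves (unrooted)."""
    names = tree.leaf_names()
    target = frozenset(n for n in names if labels.get(n) == species)
    if not target:
        raise ValidationError(f"species {species!r} has no leaf on the tree")
    if len(target) == 1 or len(target) == len(names):
        return True
    full = frozenset(names)
    for node, side in tree._leafsets():
        if node is tree.root:
            continue
        if side == target or side == full - target:
            return True
    return False


# ---------------------------------------------------------------------------
# Newick I/O and rendering


def write_newick(tree: PhyloTree, path=None, precision: int = 6) -> str:
    s = tree.to_newick(precision=precision) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s.strip()


def read_newick(source: str) -> PhyloTree:
    """Parse a Newick string; internal node labels are read as supports."""
    try:
        dtree = dendropy.Tree.get(
            data=source,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon is not None else None
        support = None
        if children and dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                name = dnode.label
        return TreeNode(
            name=name,
            length=dnode.edge.length,
            support=support,
            children=children,
        )

    root = convert(dtree.seed_node)
    return PhyloTree(root)


def ascii_render(tree: PhyloTree, display_threshold: float = 50.0, midpoint: bool = True) -> str:
    """ASCII tree for terminals; supports below the threshold are hidden.

    Midpoint rooting is applied for display only; it does not modify the
    input tree.
    """
    shown = read_newick(tree.to_newick())  # deep copy via serialization

    def scrub(n: TreeNode):
        if n.support is not None and n.support < display_threshold:
            n.support = None
        for c in n.children:
            scrub(c)

    scrub(shown.root)
    dtree = dendropy.Tree.get(data=shown.to_newick(), schema="newick",
                              suppress_internal_node_taxa=True)
    if midpoint and len(dtree.leaf_nodes()) > 2:
        dtree.reroot_at_midpoint(update_bipartitions=False)
    return dtree.as_ascii_plot(show_internal_node_labels=True)
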