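"""Distance phylogenetics: Poisson-corrected distances, neighbor joining,
bootstrap supports, monophyly, and Fitch/Hartigan parsimony.

Maximum-likelihood inference is deliberately replaced by Poisson-corrected
neighbor joining — deterministic, desk-scale, exact on additive matrices,
and sufficient for monophyly / interspersion statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EddScreenError, IncomparablePairError, TreeSizeError
from .seqio import GAP, AlignmentBlock
from .tree import PhyloTree, TreeNode

SATURATION_P = 0.95
SATURATION_CAP = 3.0

__all__ = [
    "DistanceMatrix",
    "protein_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "is_monophyletic",
    "fitch_changes",
    "path_length_matrix",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise EddScreenError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if len(set(self.taxa)) != n:
            raise EddScreenError("duplicate taxa in distance matrix")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise EddScreenError("distance matrix not symmetric within 1e-12")
        if np.any(np.diag(self.d) != 0):
            raise EddScreenError("nonzero diagonal in distance matrix")
        if np.any(self.d < 0):
            raise EddScreenError("negative distances")


def protein_distance(a: str, b: str) -> float:
    """Poisson-corrected distance between two aligned rows.

    p is the mismatch fraction over shared non-gap columns; d = -ln(1-p),
    capped at 3.0 (with a warning) when p >= 0.95.
    """
    if len(a) != len(b):
        raise EddScreenError("aligned rows differ in length")
    shared = mismatch = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        shared += 1
        if ca != cb:
            mismatch += 1
    if shared == 0:
        raise IncomparablePairError("rows share no non-gap column")
    p = mismatch / shared
    if p >= SATURATION_P:
        warnings.warn(
            f"saturated pair (p={p:.3f}); capping distance at {SATURATION_CAP}",
            stacklevel=2,
        )
        return SATURATION_CAP
    return -np.log1p(-p)


def distance_matrix(block: AlignmentBlock) -> DistanceMatrix:
    """All-pairs Poisson-corrected distances of an alignment."""
    n = len(block.rows)
    d = np.zeros((n, n))
    seqs = [r.residues for r in block.rows]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(seqs[i], seqs[j])
    return DistanceMatrix([r.id for r in block.rows], d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest member taxon).
    Negative branch lengths are clamped to zero with a warning.  Additive
    matrices are recovered exactly.
    """
    n = len(dm.taxa)
    if n < 3:
        raise TreeSizeError("neighbor joining requires at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)  # smallest taxon id per cluster
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(
                    f"negative NJ branch length {x:.3g} clamped to 0", stacklevel=3
                )
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None  # (q, label_pair, i, j)
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((labels[i], labels[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best[0], best[1], best[2]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to remaining clusters
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row[:-1]
        d[: -1, -1] = new_row[:-1]
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = sorted(active, key=lambda a: labels[a])
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


def path_length_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    taxa = tree.leaf_names
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            below = {node.name: 0.0}
        else:
            child_maps = [walk(c) for c in node.children]
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, da in child_maps[a].items():
                        for lb, db in child_maps[b].items():
                            i, j = index[la], index[lb]
                            d[i, j] = d[j, i] = da + db
            below = {}
            for cm in child_maps:
                below.update(cm)
        if node.length:
            below = {k: v + node.length for k, v in below.items()}
        return below

    walk(tree.root)
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    block: AlignmentBlock, replicates: int, seed: int | None = None
) -> PhyloTree:
    """NJ tree of the full alignment with column-bootstrap supports.

    Support of an internal edge = percentage of replicate trees containing
    the same bipartition.  Reproducible for a given seed.
    """
    if replicates < 1:
        raise EddScreenError("replicates must be >= 1")
    if block.length < 2:
        raise EddScreenError("alignment must have at least 2 columns")
    rng = np.random.default_rng(seed)
    tree = nj_tree(distance_matrix(block))

    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    seqs = [r.residues for r in block.rows]
    ids = [r.id for r in block.rows]
    L = block.length
    n = len(seqs)
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        res_seqs = ["".join(s[c] for c in cols) for s in seqs]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d[i, j] = d[j, i] = protein_distance(res_seqs[i], res_seqs[j])
        rep_bps = nj_tree(DistanceMatrix(ids, d)).bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    all_leaves = frozenset(ids)
    anchor = min(all_leaves)
    for node in tree.root.postorder():
        if node.is_leaf or node is tree.root:
            continue
        clade = frozenset(node.leaf_names())
        if len(clade) < 2 or len(all_leaves - clade) < 2:
            continue
        side = clade if anchor not in clade else all_leaves - clade
        node.support = supports.get(side)
    return tree


# ---------------------------------------------------------------------------
# monophyly and parsimony
# ---------------------------------------------------------------------------


def is_monophyletic(tree: PhyloTree, taxa) -> bool:
    """True iff some edge bipartitions the leaves into exactly (S, rest)."""
    S = frozenset(taxa)
    leaves = frozenset(tree.root.leaf_names())
    if not S:
        raise EddScreenError("empty taxon set")
    unknown = S - leaves
    if unknown:
        raise EddScreenError(f"unknown taxa {sorted(unknown)[:5]}")
    if S == leaves:
        raise EddScreenError("taxon set must be a proper subset of the leaves")
    for clade in tree.clades():
        if clade == S or leaves - clade == S:
            return True
    return False


def fitch_changes(tree: PhyloTree, labels: dict[str, str]) -> int:
    """Minimum number of character changes (small parsimony) on the tree.

    Uses Hartigan's generalisation so multifurcating nodes (including the
    trifurcating root of an unrooted tree) are scored exactly; the result
    is independent of the rooting.  ``labels`` maps every leaf to a state.
    The interspersion index equals this count; it is 1 iff either state
    set is monophyletic.
    """
    missing = [l for l in tree.root.leaf_names() if l not in labels]
    if missing:
        raise EddScreenError(f"unlabeled leaves {missing[:5]}")

    changes = 0

    def up(node: TreeNode) -> frozenset[str]:
        nonlocal changes
        if node.is_leaf:
            return frozenset([labels[node.name]])
        child_sets = [up(c) for c in node.children]
        tally: dict[str, int] = {}
        for s in child_sets:
            for state in s:
                tally[state] = tally.get(state, 0) + 1
        k_max = max(tally.values())
        changes += len(child_sets) - k_max
        return frozenset(s for s, k in tally.items() if k == k_max)

    up(tree.root)
    return changes
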