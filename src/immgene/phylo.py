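"""Gene-family trees: distances from alignments, neighbor joining, midpoint
rooting, bootstrap support, and Newick round-tripping.

Trees are :class:`skbio.TreeNode` objects.  Neighbor joining is implemented
here so that its determinism contract (tie-break by taxon label) and its
negative-branch handling (clamp to zero, move the deficit to the sibling)
are explicit; maximum-likelihood inference is out of scope and externally
built trees can be imported through the Newick interface.
"""

from __future__ import annotations

import io
import warnings
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .align import MultipleAlignment


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def msa_distances(msa: MultipleAlignment, correction: str = "p") -> DistanceMatrix:
    """Pairwise distances over mutually ungapped columns.

    ``p``: mismatch fraction.  ``poisson``: -ln(1 - p), with p capped just
    below saturation so corrected distances stay finite.  A pair with zero
    mutually ungapped columns is an error.
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = list(msa.ids)
    if len(ids) < 3:
        raise ValueError("msa_distances requires >= 3 rows")
    rows = np.array([list(msa.rows[i]) for i in ids])
    gap = rows == "-"
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no mutual coverage between {ids[i]} and {ids[j]}")
            p = float((rows[i][both] != rows[j][both]).sum()) / m
            if correction == "poisson":
                p = min(p, 1.0 - 1.0 / (m + 1))  # saturation cap
                d = -np.log(1.0 - p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Classic NJ agglomeration producing an unrooted tree (trifurcating
    base node).

    Deterministic: when several pairs minimize the Q criterion the pair with
    the lexicographically smallest sorted label pair is joined.  A negative
    branch length is clamped to zero and the deficit moved to its sibling.
    """
    ids = list(dist.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor_joining requires >= 3 taxa")
    D = np.array(dist.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    labels = list(ids)  # sort key for tie-breaks: smallest leaf label under node

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = vi
        child_j.length = vj
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        D = D2

    # attach the final three to an unrooted base node
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    lens = [va, vb, vc]
    for k in range(3):
        if lens[k] < 0:
            # split the deficit over the two siblings
            for other in range(3):
                if other != k:
                    lens[other] += lens[k] / 2.0
            lens[k] = 0.0
    for node, length in zip((a, b, c), lens):
        node.length = max(length, 0.0)
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: TreeNode) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(node, [])
        for child in node.children:
            length = child.length or 0.0
            adj[node].append((child, length))
            adj.setdefault(child, []).append((node, length))
    return adj


def _farthest(adj, start: TreeNode) -> tuple[TreeNode, float, dict]:
    """BFS over the unrooted tree; returns the farthest *leaf* (deterministic
    tie-break by name), its distance, and the predecessor map."""
    dist = {start: 0.0}
    prev: dict[TreeNode, TreeNode] = {}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, length in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + length
                prev[nbr] = node
                stack.append(nbr)
    leaves = [n for n in dist if not n.children or n is start]
    # deterministic tie-break by leaf name
    best_d = max(dist[n] for n in leaves)
    cands = sorted((n.name or "", n) for n in leaves if dist[n] == best_d)
    best = cands[0][1]
    return best, best_d, prev


def _rebuild(node: TreeNode, parent: TreeNode | None,
             adj) -> TreeNode:
    """Re-orient the unrooted tree as a rooted TreeNode hanging off ``node``,
    excluding the edge back to ``parent``."""
    clone = TreeNode(name=node.name)
    for nbr, length in adj[node]:
        if nbr is parent:
            continue
        sub = _rebuild(nbr, node, adj)
        sub.length = length
        clone.append(sub)
    return clone


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two root-side halves of that path are equal after rooting.  If every
    branch length is zero the root is placed on the edge adjacent to the
    lexicographically first leaf and a warning is emitted.
    """
    adj = _adjacency(tree)
    leaves = sorted((n.name or "", n) for n in adj if not n.children)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    total = sum(length for pairs in adj.values() for _, length in pairs)
    if total == 0.0:
        warnings.warn("all branch lengths are zero; rooting on an arbitrary "
                      "deterministic edge", stacklevel=2)
        leaf = leaves[0][1]
        parent = adj[leaf][0][0]
        root = TreeNode()
        left = TreeNode(name=leaf.name, length=0.0)
        right = _rebuild(parent, leaf, adj)
        right.length = 0.0
        root.append(left)
        root.append(right)
        return root

    u, _, _ = _farthest(adj, leaves[0][1])
    v, diameter, prev = _farthest(adj, u)
    # path v -> u via predecessor map (search started at u)
    path = [v]
    while path[-1] is not u:
        path.append(prev[path[-1]])
    path.reverse()  # u ... v
    half = diameter / 2.0
    # walk from u toward v until the midpoint falls inside an edge
    acc = 0.0
    for a, b in zip(path, path[1:]):
        length = next(l for nbr, l in adj[a] if nbr is b)
        if acc + length >= half - 1e-15:
            offset = half - acc  # distance from a along edge (a, b)
            if offset <= 1e-15:
                # midpoint sits exactly on node a: root there
                root = _rebuild(a, None, adj)
                root.length = None
                return root
            root = TreeNode()
            side_a = _rebuild(a, b, adj)
            side_a.length = offset
            side_b = _rebuild(b, a, adj)
            side_b.length = length - offset
            root.append(side_a)
            root.append(side_b)
            return root
        acc += length
    raise AssertionError("midpoint not found on the longest path")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, canonicalized as the
    side not containing the alphabetically first taxon."""
    first = min(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if not node.children:
            continue
        side = frozenset(leaf.name for leaf in node.tips())
        if first in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def default_tree_builder(msa: MultipleAlignment) -> TreeNode:
    """NJ on Poisson-corrected distances, midpoint rooted."""
    return midpoint_root(neighbor_joining(msa_distances(msa, "poisson")))


def bootstrap_support(msa: MultipleAlignment,
                      tree_builder: Callable[[MultipleAlignment], TreeNode] | None = None,
                      n_replicates: int = 100, seed: int = 0) -> TreeNode:
    """Column-resampling bootstrap.

    Builds the main tree from the full alignment, then ``n_replicates``
    replicate trees from alignments whose columns are resampled with
    replacement; each internal node of the main tree is labeled with the
    integer percentage of replicates containing its bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if tree_builder is None:
        tree_builder = default_tree_builder
    main = tree_builder(msa)
    taxa = frozenset(msa.ids)
    rng = np.random.default_rng(seed)
    ncols = msa.ncols
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rows = {i: "".join(msa.rows[i][c] for c in cols) for i in msa.ids}
        rep = tree_builder(MultipleAlignment(list(msa.ids), rows))
        for bp in _bipartitions(rep, taxa):
            counts[bp] = counts.get(bp, 0) + 1
    for node in main.traverse(include_self=False):
        if not node.children:
            continue
        side = frozenset(leaf.name for leaf in node.tips())
        if min(taxa) in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            pct = int(round(100.0 * counts.get(side, 0) / n_replicates))
            node.name = str(pct)
            node.support = pct
    return main


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds (symmetric bipartition) distance."""
    taxa = frozenset(leaf.name for leaf in t1.tips())
    taxa2 = frozenset(leaf.name for leaf in t2.tips())
    if taxa != taxa2:
        raise ValueError("trees have different taxon sets")
    b1 = _bipartitions(t1, taxa)
    b2 = _bipartitions(t2, taxa)
    return len(b1 ^ b2)


def total_length(tree: TreeNode) -> float:
    return sum((n.length or 0.0) for n in tree.traverse(include_self=False))


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(source) -> TreeNode:
    """Read a Newick tree from a path or a string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(source), format="newick")
    return TreeNode.read(str(source), format="newick")
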