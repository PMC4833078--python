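"""Independent reference implementations used only to check the package.

Each oracle is written from the defining formula or by brute force, without
reusing any code path from the package under test.
"""

from __future__ import annotations

import re

import numpy as np

NEG = float("-inf")


def sw_score_oracle(a: str, b: str, matrix, gap_open: float,
                    gap_extend: float) -> float:
    """Full Gotoh dynamic program for local alignment with affine gaps.

    Gap of length k costs gap_open + k * gap_extend.  Returns the optimal
    score (0 if no positive-scoring alignment exists).
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def motif_regex_oracle(sequence: str, pattern: str) -> list[tuple[int, int]]:
    """All (overlapping) degenerate-motif matches via a lookahead regex;
    1-based inclusive spans."""
    rx = re.compile("(?=(" + pattern.replace("X", ".") + "))")
    L = len(pattern)
    return [(m.start() + 1, m.start() + L) for m in rx.finditer(sequence)]


def pssm_window_oracle(sequence: str, matrix: np.ndarray, alphabet: str,
                       threshold: float) -> list[tuple[int, float]]:
    """Exhaustive sliding-window scoring; returns (0-based start, score) of
    every window at or above threshold."""
    L = matrix.shape[0]
    idx = {c: k for k, c in enumerate(alphabet)}
    out = []
    for i in range(len(sequence) - L + 1):
        s = sum(matrix[j, idx[sequence[i + j]]] for j in range(L))
        if s >= threshold:
            out.append((i, float(s)))
    return out


def random_additive_distances(n_leaves: int, rng: np.random.Generator):
    """Random binary tree: returns (labels, distance matrix, bipartitions).

    Distances are exactly additive over the generated topology.
    """
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    # each active node: (set of leaves, {leaf: depth below this node})
    active = [({lab}, {lab: 0.0}) for lab in labels]
    dist = {frozenset((a, b)): 0.0 for a in labels for b in labels if a != b}
    bipartitions: set[frozenset[str]] = set()
    while len(active) > 1:
        idx = sorted(rng.choice(len(active), size=2, replace=False))
        leaves_j, depth_j = active.pop(int(idx[1]))
        leaves_i, depth_i = active.pop(int(idx[0]))
        bi = float(rng.uniform(0.05, 1.0))
        bj = float(rng.uniform(0.05, 1.0))
        for la in leaves_i:
            for lb in leaves_j:
                dist[frozenset((la, lb))] = depth_i[la] + bi + depth_j[lb] + bj
        merged_leaves = leaves_i | leaves_j
        merged_depth = {k: v + bi for k, v in depth_i.items()}
        merged_depth.update({k: v + bj for k, v in depth_j.items()})
        for side in (leaves_i, leaves_j):
            if 2 <= len(side) <= n_leaves - 2:
                canon = frozenset(side)
                if labels[0] in canon:
                    canon = frozenset(set(labels) - side)
                bipartitions.add(canon)
        active.append((merged_leaves, merged_depth))
    mat = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(a + 1, n_leaves):
            mat[a, b] = mat[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, mat, bipartitions
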