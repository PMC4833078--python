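"""Distances, neighbor joining (incl. exactness on additive matrices and a
cross-check against an independent NJ implementation), midpoint rooting,
bootstrap support, and Newick round-trips."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from immgene.align import MultipleAlignment
from immgene.phylo import (bootstrap_support, midpoint_root, msa_distances,
                           neighbor_joining, read_newick, rf_distance,
                           total_length, write_newick, _bipartitions)

from oracles import random_additive_distances


def _msa(rows):
    return MultipleAlignment(list(rows), dict(rows))


def test_identical_rows_have_zero_distance():
    msa = _msa({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL", "c": "ACDEFGHIKL"})
    dm = msa_distances(msa)
    assert np.allclose(dm.data, 0.0)


def test_p_distance_counts_mutually_ungapped_columns_only():
    msa = _msa({"a": "ACDEFGHIKL", "b": "CCDEFGHIKL", "c": "-CDEFGHIKL"})
    dm = msa_distances(msa, "p")
    assert dm["a", "b"] == pytest.approx(0.1)   # 1 of 10
    assert dm["a", "c"] == pytest.approx(0.0)   # gap column excluded


def test_poisson_correction_and_saturation():
    msa = _msa({"a": "AAAAAAAAAA", "b": "AAAAACCCCC", "c": "AAAAAAAAAA"})
    dm = msa_distances(msa, "poisson")
    assert dm["a", "b"] == pytest.approx(-np.log(0.5))
    with pytest.raises(ValueError):
        msa_distances(_msa({"a": "A-", "b": "-C", "c": "AC"}), "p")


def test_distances_match_column_counting_oracle_on_fuzzed_alignments():
    rng = np.random.default_rng(71)
    letters = np.array(list("ACDEFG-"))
    for _ in range(50):
        n, m = int(rng.integers(3, 7)), int(rng.integers(10, 40))
        rows = {}
        for i in range(n):
            rows[f"t{i}"] = "".join(rng.choice(letters, size=m))
        try:
            dm = msa_distances(_msa(rows), "p")
        except ValueError:
            continue  # a pair with zero mutual coverage
        ids = sorted(rows)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = rows[ids[i]], rows[ids[j]]
                cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
                p = sum(x != y for x, y in cols) / len(cols)
                assert dm[ids[i], ids[j]] == pytest.approx(p)


def test_three_taxon_closed_form():
    dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                        ["A", "B", "C"])
    tree = neighbor_joining(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_duplicate_taxon_distance_zero_gives_zero_length_cherry():
    d = np.array([[0, 0, 3, 3], [0, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
                 float)
    tree = neighbor_joining(DistanceMatrix(d, ["A", "Adup", "C", "D"]))
    a = tree.find("A")
    assert a.length == pytest.approx(0.0)
    sibling_names = {t.name for t in a.parent.tips()}
    assert sibling_names == {"A", "Adup"}


def test_nj_exact_on_random_additive_matrices():
    """Topology recovery (RF = 0) and exact path lengths from additive
    matrices of random 8-leaf trees."""
    rng = np.random.default_rng(72)
    for _ in range(30):
        labels, mat, true_biparts = random_additive_distances(8, rng)
        tree = neighbor_joining(DistanceMatrix(mat, labels))
        got = _bipartitions(tree, frozenset(labels))
        assert got == true_biparts
        # leaf-to-leaf path lengths reproduce the input distances
        dists = tree.tip_tip_distances()
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                assert abs(dists[a, labels[j]] - mat[i, j]) < 1e-9


def test_nj_matches_independent_implementation_topology():
    """Cross-check against scikit-bio's own NJ on noisy (non-additive)
    matrices: identical topologies."""
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(73)
    for _ in range(10):
        labels, mat, _ = random_additive_distances(7, rng)
        noise = rng.uniform(0, 0.01, size=mat.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dm = DistanceMatrix(mat + noise, labels)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert rf_distance(ours, theirs) == 0


def test_nj_requires_three_taxa_and_symmetry():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))


def test_midpoint_two_leaves_splits_path_in_half():
    tree = read_newick("(A:1,B:3);")
    rooted = midpoint_root(tree)
    depths = {t.name: rooted.distance(t) for t in rooted.tips()}
    assert depths["A"] == pytest.approx(2.0)
    assert depths["B"] == pytest.approx(2.0)


def test_midpoint_symmetric_quartet_roots_on_central_edge():
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    rooted = midpoint_root(tree)
    kids = {frozenset(t.name for t in ch.tips()) for ch in rooted.children}
    assert kids == {frozenset({"A", "B"}), frozenset({"C", "D"})}


def test_midpoint_zero_length_tree_is_deterministic_with_warning():
    tree = read_newick("((A:0,B:0):0,C:0);")
    with pytest.warns(UserWarning, match="zero"):
        r1 = midpoint_root(tree)
    with pytest.warns(UserWarning):
        r2 = midpoint_root(read_newick("((A:0,B:0):0,C:0);"))
    assert str(r1) == str(r2)


def test_midpoint_path_audit_and_invariance_on_random_trees():
    """After rooting: the two deepest root-side paths are equal halves of
    the diameter; topology and total length are unchanged."""
    rng = np.random.default_rng(74)
    for _ in range(50):
        labels, mat, biparts = random_additive_distances(
            int(rng.integers(4, 10)), rng)
        tree = neighbor_joining(DistanceMatrix(mat, labels))
        before_len = total_length(tree)
        rooted = midpoint_root(tree)
        depths = sorted((rooted.distance(t) for t in rooted.tips()),
                        reverse=True)
        diameter = mat.max()
        assert abs(depths[0] - diameter / 2) < 1e-9
        # deepest leaves on the two sides are both at half the diameter
        side_depths = []
        for child in rooted.children:
            below = [child.distance(t) for t in child.tips()] or [0.0]
            side_depths.append((child.length or 0.0) + max(below))
        assert abs(side_depths[0] - side_depths[1]) < 1e-9
        assert abs(total_length(rooted) - before_len) < 1e-9
        assert _bipartitions(rooted, frozenset(labels)) == biparts


def test_bootstrap_single_replicate_supports_are_0_or_100():
    rng = np.random.default_rng(75)
    rows = {f"t{i}": "".join(rng.choice(list("ACDE"), size=30))
            for i in range(5)}
    msa = _msa(rows)
    tree = bootstrap_support(msa, n_replicates=1, seed=0)
    sups = [n.support for n in tree.traverse(include_self=False)
            if n.children and getattr(n, "support", None) is not None]
    assert sups and all(s in (0, 100) for s in sups)


def test_bootstrap_is_deterministic_under_fixed_seed():
    rng = np.random.default_rng(76)
    rows = {f"t{i}": "".join(rng.choice(list("ACDEFGHIKL"), size=40))
            for i in range(6)}
    t1 = bootstrap_support(_msa(rows), n_replicates=20, seed=5)
    t2 = bootstrap_support(_msa(rows), n_replicates=20, seed=5)
    assert str(t1) == str(t2)


def test_newick_round_trip_preserves_lengths_and_supports(tmp_path):
    rng = np.random.default_rng(77)
    labels, mat, _ = random_additive_distances(6, rng)
    tree = midpoint_root(neighbor_joining(DistanceMatrix(mat, labels)))
    for k, node in enumerate(tree.traverse(include_self=False)):
        if node.children:
            node.name = str(50 + k)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert rf_distance(tree, back) == 0
    orig = {frozenset(t.name for t in n.tips()): (n.name, n.length)
            for n in tree.traverse(include_self=False) if n.children}
    readback = {frozenset(t.name for t in n.tips()): (n.name, n.length)
                for n in back.traverse(include_self=False) if n.children}
    for key, (name, length) in orig.items():
        assert readback[key][0] == name
        assert abs(readback[key][1] - length) < 1e-9
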