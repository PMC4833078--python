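"""Threshold filters, reciprocal best hits, orthogroup clustering, and
haplotype collapsing."""

import numpy as np
import pandas as pd
import pytest

from immgene.homology import (HIT_COLUMNS, all_vs_all_search,
                              best_reciprocal_hits, cluster_orthogroups,
                              collapse_haplotypes, empty_hit_table,
                              filter_hits_blast, filter_hits_profile,
                              global_identity, read_hit_table,
                              write_hit_table)
from immgene.io_formats import ProteinRecord
from immgene.synthetic_data import mutate

from conftest import random_protein


def _row(evalue, identity, bitscore, q=("A", "a1"), s=("B", "b1")):
    return (q[0], q[1], s[0], s[1], identity, 100, evalue, bitscore, bitscore)


def _table(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def test_blast_filter_applies_published_cutoffs():
    t = _table([_row(1e-7, 0.35, 100),   # passes all three
                _row(1e-5, 0.35, 100),   # e-value too large
                _row(1e-7, 0.15, 100)])  # identity too low
    out = filter_hits_blast(t)
    assert len(out) == 1 and out.iloc[0]["evalue"] == 1e-7


def test_blast_filter_thresholds_are_strict_inequalities():
    """12 synthetic rows straddling each stated cutoff; survivors equal
    hand enumeration."""
    rows = [
        _row(1e-7, 0.35, 100),    # keep
        _row(1e-6, 0.35, 100),    # drop: e == 1e-6 not < 1e-6
        _row(9.9e-7, 0.35, 100),  # keep
        _row(1e-3, 0.35, 100),    # drop
        _row(1e-7, 0.20, 100),    # drop: identity == 0.20 not > 0.20
        _row(1e-7, 0.201, 100),   # keep
        _row(1e-7, 0.05, 100),    # drop
        _row(1e-7, 0.99, 100),    # keep
        _row(1e-7, 0.35, 80),     # drop: bitscore == 80 not > 80
        _row(1e-7, 0.35, 80.5),   # keep
        _row(1e-7, 0.35, 10),     # drop
        _row(1e-8, 0.5, 300),     # keep
    ]
    out = filter_hits_blast(_table(rows))
    assert len(out) == 6


def test_profile_filter_strict_less_than():
    t = _table([_row(9e-6, 0.9, 50), _row(1e-5, 0.9, 50)])
    out = filter_hits_profile(t)
    assert len(out) == 1 and out.iloc[0]["evalue"] == 9e-6


def test_filters_are_idempotent_and_tolerate_empty():
    assert filter_hits_blast(empty_hit_table()).empty
    assert filter_hits_profile(empty_hit_table()).empty
    t = _table([_row(1e-7, 0.35, 100), _row(1e-5, 0.35, 100)])
    once = filter_hits_blast(t)
    twice = filter_hits_blast(once)
    pd.testing.assert_frame_equal(once, twice)


def test_rbh_mutual_top_hits_and_reciprocity():
    # two species, one gene each, mutual top hits -> one pair
    t = _table([_row(1e-9, 0.9, 200, q=("sp", "x1"), s=("ref", "r1")),
                _row(1e-9, 0.9, 200, q=("ref", "r1"), s=("sp", "x1"))])
    assert best_reciprocal_hits(t, "ref") == [("r1", ("sp", "x1"))]
    # x1's best is r1 but r1's best is x2 -> no pair for x1
    t2 = _table([
        _row(1e-9, 0.9, 200, q=("sp", "x1"), s=("ref", "r1")),
        _row(1e-9, 0.9, 150, q=("ref", "r1"), s=("sp", "x1")),
        _row(1e-9, 0.9, 300, q=("ref", "r1"), s=("sp", "x2")),
        _row(1e-9, 0.9, 300, q=("sp", "x2"), s=("ref", "r1")),
    ])
    pairs = best_reciprocal_hits(t2, "ref")
    assert pairs == [("r1", ("sp", "x2"))]


def test_rbh_recovers_planted_orthologs_in_synthetic_proteomes():
    """3 species x 10 genes, orthologs at low divergence: recovered pairs
    equal the planted truth."""
    rng = np.random.default_rng(21)
    ancestors = [random_protein(rng, 120) for _ in range(10)]
    records = []
    for sp in ("ref", "spA", "spB"):
        for g, anc in enumerate(ancestors):
            records.append(ProteinRecord(sp, f"g{g}", mutate(anc, 0.05, rng)))
    hits = filter_hits_blast(all_vs_all_search(records))
    pairs = best_reciprocal_hits(hits, "ref")
    expected = {(f"g{g}", (sp, f"g{g}"))
                for g in range(10) for sp in ("spA", "spB")}
    assert set(pairs) == expected


def test_orthogroups_partition_with_no_edges():
    prots = [("a", "p1"), ("a", "p2"), ("b", "p1")]
    groups = cluster_orthogroups(empty_hit_table(), prots)
    assert len(groups) == 3
    assert sorted(m for g in groups for m in g.members) == sorted(prots)


def test_orthogroups_from_hand_drawn_graph_components():
    # component 1: a1-b1-c1 (path); component 2: a2-b2; singleton: c3
    def both(q, s):
        return [_row(1e-9, 0.9, 200, q=q, s=s), _row(1e-9, 0.9, 200, q=s, s=q)]
    rows = (both(("a", "1"), ("b", "1")) + both(("b", "1"), ("c", "1"))
            + both(("a", "2"), ("b", "2")))
    prots = [("a", "1"), ("b", "1"), ("c", "1"), ("a", "2"), ("b", "2"),
             ("c", "3")]
    groups = cluster_orthogroups(_table(rows), prots)
    sizes = sorted(len(g.members) for g in groups)
    assert sizes == [1, 2, 3]
    # partition: disjoint and covering
    everything = [m for g in groups for m in g.members]
    assert sorted(everything) == sorted(prots)


def test_orthogroup_family_label_propagates_from_reference_query():
    def both(q, s):
        return [_row(1e-9, 0.9, 200, q=q, s=s), _row(1e-9, 0.9, 200, q=s, s=q)]
    rows = both(("ref", "q1"), ("sp", "x1")) + both(("sp", "x1"), ("sp", "x2"))
    groups = cluster_orthogroups(
        _table(rows), [("ref", "q1"), ("sp", "x1"), ("sp", "x2")],
        query_families={"q1": "PGRP"}, reference_species="ref")
    g = next(g for g in groups if len(g.members) == 3)
    assert g.family == "PGRP" and g.contains_reference_query


def test_orthogroup_conflicting_labels_flagged_ambiguous():
    def both(q, s):
        return [_row(1e-9, 0.9, 200, q=q, s=s), _row(1e-9, 0.9, 200, q=s, s=q)]
    rows = both(("ref", "q1"), ("ref", "q2"))
    groups = cluster_orthogroups(
        _table(rows), [("ref", "q1"), ("ref", "q2")],
        query_families={"q1": "PGRP", "q2": "TEP"}, reference_species="ref")
    g = groups[0]
    assert g.ambiguous and g.family is None


def test_one_directional_hits_do_not_form_edges():
    rows = [_row(1e-9, 0.9, 200, q=("a", "1"), s=("b", "1"))]  # no reciprocal
    groups = cluster_orthogroups(_table(rows), [("a", "1"), ("b", "1")])
    assert len(groups) == 2


def test_collapse_merges_identical_keeps_longer_and_reports():
    recs = [ProteinRecord("sp", "frag", "MKVLTTACDEFGHIKNP"),
            ProteinRecord("sp", "full", "MKVLTTACDEFGHIKNPQ")]
    kept, report = collapse_haplotypes(recs, identity_threshold=0.94)
    assert [r.protein_id for r in kept] == ["full"]
    assert len(report.merges) == 1 and report.merges[0][:2] == ("full", "frag")
    # exact duplicates of equal length: lexicographically first id survives
    dup = [ProteinRecord("sp", "b", "MKVLTTACDEFGHIKNPQ"),
           ProteinRecord("sp", "a", "MKVLTTACDEFGHIKNPQ")]
    kept2, report2 = collapse_haplotypes(dup)
    assert [r.protein_id for r in kept2] == ["a"]
    assert report2.merges == [("a", "b", 1.0)]


def test_collapse_respects_threshold():
    rng = np.random.default_rng(22)
    base = random_protein(rng, 100)
    variant = mutate(base, 0.05, rng)  # ~95% identity
    assert global_identity(base, variant) < 0.99
    recs = [ProteinRecord("sp", "a", base), ProteinRecord("sp", "b", variant)]
    kept, report = collapse_haplotypes(recs, identity_threshold=0.99)
    assert len(kept) == 2 and not report.merges


def test_collapse_planted_near_duplicates():
    """10 sequences with 3 planted 99.5%-identity duplicates -> 7 survive."""
    rng = np.random.default_rng(23)
    recs = [ProteinRecord("sp", f"p{i}", random_protein(rng, 200))
            for i in range(7)]
    for k in range(3):
        seq = list(recs[k].sequence)
        seq[10] = "W" if seq[10] != "W" else "Y"  # 1 of 200 differs: 99.5%
        recs.append(ProteinRecord("sp", f"dup{k}", "".join(seq)))
    kept, report = collapse_haplotypes(recs, identity_threshold=0.99)
    assert len(kept) == 7 and len(report.merges) == 3


def test_hit_table_tabular_round_trip(tmp_path):
    t = _table([_row(1e-9, 0.912, 203.4), _row(2e-8, 0.5, 99.0,
                                               q=("c", "z"), s=("d", "w"))])
    path = tmp_path / "hits.tsv"
    write_hit_table(t, path)
    back = read_hit_table(path)
    assert list(back["query_id"]) == ["a1", "z"]
    assert np.allclose(back["identity"], t["identity"], atol=5e-5)
    assert np.allclose(back["evalue"], t["evalue"], rtol=1e-2)
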