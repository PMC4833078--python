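"""Candidate generation: all-vs-all protein search, published-threshold
filtering, best reciprocal hits against the reference species, orthogroup
clustering, and haplotype-duplicate collapsing.

Hit tables are pandas DataFrames with the columns in :data:`HIT_COLUMNS`.
Orthogroup clustering follows the all-vs-all + clustering strategy of
large-scale orthology tools, simplified to connected components over
reciprocal filtered hits so the behaviour is deterministic and checkable at
desk scale.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .align import smith_waterman
from .io_formats import ProteinRecord

HIT_COLUMNS = ["query_species", "query_id", "subject_species", "subject_id",
               "identity", "aln_length", "evalue", "bitscore", "score"]

#: published search-significance thresholds
BLAST_EVALUE = 1e-6
BLAST_IDENTITY = 0.20
BLAST_BITSCORE = 80.0
PROFILE_EVALUE = 1e-5


def empty_hit_table() -> pd.DataFrame:
    return pd.DataFrame(columns=HIT_COLUMNS)


@dataclass
class Orthogroup:
    group_id: str
    members: list[tuple[str, str]]  # (species, protein_id)
    contains_reference_query: bool = False
    family: str | None = None
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _kmer_candidates(records: Sequence[ProteinRecord], k: int = 5,
                     min_shared: int = 2) -> set[tuple[int, int]]:
    """Candidate index pairs sharing at least ``min_shared`` k-mers.

    A cheap word-match prescreen in the spirit of seeded search tools: pairs
    with fewer shared words than random expectation cannot reach the
    significance thresholds downstream, so they are never aligned.
    """
    postings: dict[str, list[int]] = defaultdict(list)
    for idx, rec in enumerate(records):
        seen = set()
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if w not in seen:
                seen.add(w)
                postings[w].append(idx)
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for idxs in postings.values():
        if len(idxs) < 2 or len(idxs) > 50:  # drop low-complexity words
            continue
        for a, b in itertools.combinations(idxs, 2):
            counts[(a, b)] += 1
    return {pair for pair, c in counts.items() if c >= min_shared}


def all_vs_all_search(records: Sequence[ProteinRecord], gap_open: float = 11.0,
                      gap_extend: float = 1.0, k: int = 5,
                      min_shared_kmers: int = 2) -> pd.DataFrame:
    """All-vs-all local-alignment search over a set of proteomes.

    Each candidate pair (after the k-mer prescreen) is aligned once; the
    symmetric hit is emitted in both directions.  Self-hits are never
    retained.  Rows are sorted for determinism.
    """
    recs = sorted(records, key=lambda r: r.key)
    pairs = _kmer_candidates(recs, k=k, min_shared=min_shared_kmers)
    rows = []
    for a, b in sorted(pairs):
        ra, rb = recs[a], recs[b]
        if ra.key == rb.key:
            continue
        aln = smith_waterman(ra.sequence, rb.sequence,
                             gap_open=gap_open, gap_extend=gap_extend)
        if aln.is_empty:
            continue
        length = len(aln.aligned_pairs)
        rows.append((ra.species, ra.protein_id, rb.species, rb.protein_id,
                     aln.identity_fraction, length, aln.evalue, aln.bitscore,
                     aln.score))
        rows.append((rb.species, rb.protein_id, ra.species, ra.protein_id,
                     aln.identity_fraction, length, aln.evalue, aln.bitscore,
                     aln.score))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(HIT_COLUMNS[:4], ignore_index=True)


# ---------------------------------------------------------------------------
# Threshold filters
# ---------------------------------------------------------------------------

def filter_hits_blast(table: pd.DataFrame) -> pd.DataFrame:
    """Keep rows with e-value < 1e-6 AND identity > 20% AND bit score > 80
    (strict inequalities, exactly as published)."""
    if table.empty:
        return table.copy()
    keep = ((table["evalue"] < BLAST_EVALUE)
            & (table["identity"] > BLAST_IDENTITY)
            & (table["bitscore"] > BLAST_BITSCORE))
    return table[keep].reset_index(drop=True)


def filter_hits_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Keep rows with e-value < 1e-5 (strict), the profile-search cutoff."""
    if table.empty:
        return table.copy()
    return table[table["evalue"] < PROFILE_EVALUE].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _top_hit(group: pd.DataFrame) -> pd.Series:
    """Best row: max bitscore, ties by lower evalue then lexicographic id."""
    g = group.sort_values(["bitscore", "evalue", "subject_id"],
                          ascending=[False, True, True], kind="mergesort")
    return g.iloc[0]


def best_reciprocal_hits(table: pd.DataFrame, reference_species: str,
                         ) -> list[tuple[str, tuple[str, str]]]:
    """Reciprocal best hits against the reference species.

    Returns pairs (reference protein id, (species, protein id)) such that
    each is the other's top-scoring hit in the respective proteome.
    """
    if table.empty:
        return []
    to_ref = table[(table["subject_species"] == reference_species)
                   & (table["query_species"] != reference_species)]
    from_ref = table[(table["query_species"] == reference_species)
                     & (table["subject_species"] != reference_species)]
    best_to_ref: dict[tuple[str, str], str] = {}
    for (qs, qid), grp in to_ref.groupby(["query_species", "query_id"], sort=True):
        best_to_ref[(qs, qid)] = _top_hit(grp)["subject_id"]
    best_from_ref: dict[tuple[str, str], str] = {}
    for (rid, ss), grp in from_ref.groupby(["query_id", "subject_species"], sort=True):
        best_from_ref[(rid, ss)] = _top_hit(grp)["subject_id"]
    out = []
    for (sp, pid), rid in sorted(best_to_ref.items()):
        if best_from_ref.get((rid, sp)) == pid:
            out.append((rid, (sp, pid)))
    return out


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

def cluster_orthogroups(filtered: pd.DataFrame,
                        proteins: Sequence[tuple[str, str]],
                        query_families: Mapping[str, str] | None = None,
                        reference_species: str | None = None,
                        ) -> list[Orthogroup]:
    """Connected components of the reciprocal filtered-hit graph.

    Every input protein lands in exactly one group (singletons allowed).
    A group is labeled with a family when it contains a reference-species
    query protein carrying that label; conflicting labels flag the group
    ambiguous instead of being silently resolved.
    """
    g = nx.Graph()
    g.add_nodes_from(proteins)
    if not filtered.empty:
        directed = set(zip(zip(filtered["query_species"], filtered["query_id"]),
                           zip(filtered["subject_species"], filtered["subject_id"])))
        for a, b in directed:
            if (b, a) in directed and a != b:
                g.add_edge(a, b)
    groups = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for n, comp in enumerate(comps):
        members = sorted(comp)
        labels = set()
        has_query = False
        if query_families is not None and reference_species is not None:
            for sp, pid in members:
                if sp == reference_species and pid in query_families:
                    has_query = True
                    labels.add(query_families[pid])
        og = Orthogroup(group_id=f"OG{n:04d}", members=members,
                        contains_reference_query=has_query)
        if len(labels) == 1:
            og.family = labels.pop()
        elif len(labels) > 1:
            og.ambiguous = True
        groups.append(og)
    return groups


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def global_identity(seq_a: str, seq_b: str) -> float:
    """Global identity = 1 - edit distance / max length."""
    d = edlib.align(seq_a, seq_b, task="distance")["editDistance"]
    return 1.0 - d / max(len(seq_a), len(seq_b))


@dataclass
class CollapseReport:
    merges: list[tuple[str, str, float]] = field(default_factory=list)
    # (kept id, removed id, identity)


def collapse_haplotypes(records: Sequence[ProteinRecord],
                        identity_threshold: float = 0.99,
                        ) -> tuple[list[ProteinRecord], CollapseReport]:
    """Merge within-species near-duplicates (suspected split haplotypes).

    Pairs with global identity >= threshold are unioned; the longest
    sequence of each union survives (ties by lexicographic id).  The report
    lists each removed record with its surviving partner.
    """
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValueError("collapse_haplotypes expects records from one species")
    recs = sorted(records, key=lambda r: r.protein_id)
    n = len(recs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pair_identity: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            la, lb = len(recs[i]), len(recs[j])
            if min(la, lb) / max(la, lb) < identity_threshold:
                continue  # length difference alone already breaks the bound
            ident = global_identity(recs[i].sequence, recs[j].sequence)
            if ident >= identity_threshold:
                pair_identity[(i, j)] = ident
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        clusters[find(i)].append(i)
    survivors = []
    report = CollapseReport()
    for root in sorted(clusters, key=lambda r: recs[clusters[r][0]].protein_id):
        idxs = clusters[root]
        keep = sorted(idxs, key=lambda i: (-len(recs[i]), recs[i].protein_id))[0]
        survivors.append(recs[keep])
        for i in idxs:
            if i == keep:
                continue
            key = (min(i, keep), max(i, keep))
            ident = pair_identity.get(key, global_identity(
                recs[i].sequence, recs[keep].sequence))
            report.merges.append((recs[keep].protein_id, recs[i].protein_id, ident))
    survivors.sort(key=lambda r: r.protein_id)
    report.merges.sort()
    return survivors, report


# ---------------------------------------------------------------------------
# Tabular interchange (12-column search-tool layout)
# ---------------------------------------------------------------------------

def write_hit_table(table: pd.DataFrame, path) -> None:
    """Export in the standard 12-column tabular layout, with species encoded
    as ``species|protein_id`` so real search output can be dropped in."""
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            q = f"{r.query_species}|{r.query_id}"
            s = f"{r.subject_species}|{r.subject_id}"
            fh.write(f"{q}\t{s}\t{100.0 * r.identity:.2f}\t{int(r.aln_length)}\t"
                     f"0\t0\t0\t0\t0\t0\t{r.evalue:.3g}\t{r.bitscore:.1f}\n")


def read_hit_table(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            qs, qid = f[0].split("|", 1)
            ss, sid = f[1].split("|", 1)
            rows.append((qs, qid, ss, sid, float(f[2]) / 100.0, int(f[3]),
                         float(f[10]), float(f[11]), float(f[11])))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
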