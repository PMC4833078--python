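"""Pairwise local alignment, progressive multiple alignment, and the
alignment-column <-> sequence-position maps that anchor all residue-based
functional calls.

Scoring conventions
-------------------
* Substitution matrix defaults to BLOSUM62 with the ambiguity letter X made
  neutral (score 0 against everything).
* Gap penalties follow the search-tool convention: a gap of length ``k``
  costs ``gap_open + k * gap_extend`` (so the defaults 11/1 charge 12 for the
  first gapped residue).  Defaults are the standard protein-search settings.
* Bit scores and e-values use fixed Karlin–Altschul constants for gapped
  BLOSUM62-11/1 searches (K = 0.041, lambda = 0.267); they serve only to
  apply published significance thresholds, not as calibrated statistics.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ALPHABET, ProteinRecord

KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@functools.lru_cache(maxsize=None)
def default_matrix() -> substitution_matrices.Array:
    """BLOSUM62 with the X row/column zeroed (X scores neutral everywhere)."""
    m = substitution_matrices.load("BLOSUM62")
    for letter in m.alphabet:
        m["X", letter] = 0.0
        m[letter, "X"] = 0.0
    return m


@functools.lru_cache(maxsize=None)
def matrix_as_array(matrix_key: str = "default") -> np.ndarray:
    """The default matrix as a dense 21x21 array over :data:`ALPHABET`."""
    m = default_matrix()
    out = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a, b]
    return out


def encode(seq: str) -> np.ndarray:
    """Integer-encode a sequence over :data:`ALPHABET`."""
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


@dataclass
class PairwiseAlignment:
    """Optimal local alignment of two sequences under affine-gap scoring.

    Ranges are 0-based half-open on the respective sequences; ``aligned_pairs``
    holds the matched (i, j) residue index pairs, in order.  An empty
    alignment (no positive-scoring pair) has score 0 and empty ranges.
    """

    query_id: str
    subject_id: str
    score: float
    bitscore: float
    evalue: float
    identity_fraction: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    aligned_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.aligned_pairs


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open on the first gapped residue; convert from the
    # open + k*extend convention used here.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(seq_a: str, seq_b: str, matrix=None,
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   query_id: str = "query", subject_id: str = "subject",
                   K: float = KARLIN_K, lam: float = KARLIN_LAMBDA,
                   ) -> PairwiseAlignment:
    """Optimal Smith–Waterman local alignment with affine gaps.

    Deterministic: of all optimal tracebacks the first alignment in
    Biopython's enumeration order is reported; the score is unique.
    """
    if not seq_a or not seq_b:
        raise ValueError("smith_waterman: sequences must be non-empty")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("smith_waterman: gap penalties must be positive")
    if matrix is None:
        matrix = default_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        bit, ev = karlin_evalue(0.0, len(seq_a), len(seq_b), K=K, lam=lam)
        return PairwiseAlignment(query_id, subject_id, 0.0, bit, ev, 0.0,
                                 (0, 0), (0, 0), ())
    aln = next(iter(aligner.align(seq_a, seq_b)))
    pairs: list[tuple[int, int]] = []
    ident = 0
    (a_blocks, b_blocks) = aln.aligned
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                ident += 1
    qr = (pairs[0][0], pairs[-1][0] + 1)
    sr = (pairs[0][1], pairs[-1][1] + 1)
    bit, ev = karlin_evalue(score, len(seq_a), len(seq_b), K=K, lam=lam)
    return PairwiseAlignment(
        query_id, subject_id, float(score), bit, ev,
        ident / len(pairs), qr, sr, tuple(pairs),
    )


def karlin_evalue(score: float, len_a: int, len_b: int,
                  K: float = KARLIN_K, lam: float = KARLIN_LAMBDA,
                  ) -> tuple[float, float]:
    """Karlin–Altschul bit score and e-value for a raw alignment score.

    bitscore = (lambda*S - ln K) / ln 2;  evalue = K*m*n*exp(-lambda*S).
    """
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    bitscore = (lam * score - math.log(K)) / math.log(2)
    evalue = K * len_a * len_b * math.exp(-lam * score)
    return bitscore, evalue


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """Ordered gapped rows of equal length; degapping a row reproduces the
    member sequence exactly."""

    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    def degapped(self, member_id: str) -> str:
        return self.rows[member_id].replace("-", "")

    def column(self, col0: int) -> str:
        return "".join(self.rows[i][col0] for i in self.ids)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i in self.ids:
                fh.write(f">{i}\n{self.rows[i]}\n")


@dataclass(frozen=True)
class ResidueAnchor:
    """Named reference positions with their expected residue letters.

    Positions are 1-based in the (ungapped) reference sequence; ``expected``
    holds an allowed-letter set per position.
    """

    anchor_id: str
    reference_id: str
    positions: tuple[int, ...]
    expected: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError(f"anchor {self.anchor_id}: positions must be strictly increasing")
        if len(self.positions) != len(self.expected):
            raise ValueError(f"anchor {self.anchor_id}: positions/expected length mismatch")

    def shifted(self, offset: int) -> "ResidueAnchor":
        """Anchor with all positions shifted by ``offset`` (e.g. into a
        domain-local coordinate system)."""
        return ResidueAnchor(self.anchor_id, self.reference_id,
                             tuple(p + offset for p in self.positions), self.expected)


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """Per-column letter frequencies (gaps contribute zero mass)."""
    ncols = len(rows[0])
    out = np.zeros((ncols, len(ALPHABET)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                out[c, _AA_INDEX[ch]] += 1.0
    return out / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str], score_mat: np.ndarray,
                    gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Global affine profile–profile alignment; returns the two row groups
    padded with gap columns to a common length."""
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    S = fa @ score_mat @ fb.T
    n, m = S.shape
    NEG = -1e18
    go = gap_open + gap_extend  # cost of the first gapped column
    ge = gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -go - ge * (j - 1)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        Si = S[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        pM, pX = ptrM[i], ptrX[i]
        pY = ptrY[i]
        for j in range(1, m + 1):
            # match state: best predecessor at (i-1, j-1)
            a, b, c = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            if a >= b and a >= c:
                Mi[j] = a + Si[j - 1]; pM[j] = 0
            elif b >= c:
                Mi[j] = b + Si[j - 1]; pM[j] = 1
            else:
                Mi[j] = c + Si[j - 1]; pM[j] = 2
            # X: gap in B
            a, b = Mi1[j] - go, Xi1[j] - ge
            if a >= b:
                Xi[j] = a; pX[j] = 0
            else:
                Xi[j] = b; pX[j] = 1
            # Y: gap in A
            a, b = Mi[j - 1] - go, Yi[j - 1] - ge
            if a >= b:
                Yi[j] = a; pY[j] = 0
            else:
                Yi[j] = b; pY[j] = 2
    # traceback from best final state (tie-break M > X > Y)
    finals = (M[n, m], X[n, m], Y[n, m])
    if finals[0] >= finals[1] and finals[0] >= finals[2]:
        state = 0
    elif finals[1] >= finals[2]:
        state = 1
    else:
        state = 2
    i, j = n, m
    path: list[tuple[bool, bool]] = []  # (consume A, consume B)
    while i > 0 or j > 0:
        if i == 0:
            path.append((False, True)); j -= 1; continue
        if j == 0:
            path.append((True, False)); i -= 1; continue
        if state == 0:
            path.append((True, True))
            state = ptrM[i, j]; i -= 1; j -= 1
        elif state == 1:
            path.append((True, False))
            state = ptrX[i, j]; i -= 1
        else:
            path.append((False, True))
            state = ptrY[i, j]; j -= 1
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = jb = 0
    for consume_a, consume_b in path:
        for k, row in enumerate(rows_a):
            out_a[k] += row[ia] if consume_a else "-"
        for k, row in enumerate(rows_b):
            out_b[k] += row[jb] if consume_b else "-"
        if consume_a:
            ia += 1
        if consume_b:
            jb += 1
    return out_a, out_b


def progressive_msa(records: Sequence[ProteinRecord], matrix=None,
                    gap_open: float = 11.0, gap_extend: float = 1.0,
                    ) -> MultipleAlignment:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on pairwise distances 1 - identity_fraction
    of local alignments; profiles are merged leaf-to-root with the same
    affine scoring used pairwise.  A single record passes through unaligned.
    """
    if not records:
        raise ValueError("progressive_msa: no records")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("progressive_msa: duplicate member ids")
    seqs = {r.protein_id: r.sequence for r in records}
    if len(records) == 1:
        return MultipleAlignment([ids[0]], {ids[0]: seqs[ids[0]]})
    score_mat = matrix_as_array()

    def merge(group_a: list[str], group_b: list[str],
              rows: dict[str, str]) -> dict[str, str]:
        new_a, new_b = _align_profiles([rows[i] for i in group_a],
                                       [rows[i] for i in group_b],
                                       score_mat, gap_open, gap_extend)
        merged = {}
        for gid, row in zip(group_a, new_a):
            merged[gid] = row
        for gid, row in zip(group_b, new_b):
            merged[gid] = row
        return merged

    if len(records) == 2:
        rows = {ids[0]: seqs[ids[0]], ids[1]: seqs[ids[1]]}
        rows = merge([ids[0]], [ids[1]], rows)
        return MultipleAlignment(list(ids), rows)

    # guide tree
    from . import phylo
    from skbio import DistanceMatrix

    n = len(ids)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = smith_waterman(seqs[ids[i]], seqs[ids[j]], matrix=matrix,
                                 gap_open=gap_open, gap_extend=gap_extend)
            d = 1.0 - aln.identity_fraction
            dmat[i, j] = dmat[j, i] = d
    guide = phylo.neighbor_joining(DistanceMatrix(dmat, ids))

    rows: dict[str, str] = dict(seqs)
    order: list[str] = []

    def resolve(node) -> list[str]:
        if node.is_tip():
            return [node.name]
        groups = [resolve(ch) for ch in node.children]
        current = groups[0]
        for grp in groups[1:]:
            merged = merge(current, grp, rows)
            rows.update(merged)
            current = current + grp
        return current

    order = resolve(guide)
    # keep input order in the output for readability
    ordered = [i for i in ids]
    return MultipleAlignment(ordered, {i: rows[i] for i in ordered})


# ---------------------------------------------------------------------------
# Column/position maps and anchored residue states
# ---------------------------------------------------------------------------

def map_reference_position(msa: MultipleAlignment, reference_id: str,
                           ref_pos_1based: int) -> int:
    """Alignment column (1-based) holding the reference's residue at the
    given 1-based ungapped position."""
    if reference_id not in msa.rows:
        raise KeyError(f"{reference_id} not in alignment")
    row = msa.rows[reference_id]
    if not 1 <= ref_pos_1based <= len(row) - row.count("-"):
        raise ValueError(f"position {ref_pos_1based} beyond reference length")
    seen = 0
    for col0, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == ref_pos_1based:
                return col0 + 1
    raise AssertionError("unreachable")


def column_to_position(msa: MultipleAlignment, member_id: str,
                       col_1based: int) -> int | None:
    """Inverse map: the member's 1-based residue position at an alignment
    column, or None when the member is gapped there."""
    row = msa.rows[member_id]
    if not 1 <= col_1based <= len(row):
        raise ValueError(f"column {col_1based} out of range")
    if row[col_1based - 1] == "-":
        return None
    return col_1based - row[:col_1based].count("-")


@dataclass(frozen=True)
class AnchorState:
    """Residue letters observed at each anchored position for one member."""

    member_id: str
    anchor_id: str
    letters: tuple[str, ...]          # '-' where the member is gapped
    all_expected: bool


def residue_state_at_anchor(msa: MultipleAlignment, member_id: str,
                            anchor: ResidueAnchor) -> AnchorState:
    """Report the member's letters in the columns anchored by the reference,
    and whether every position holds an expected letter."""
    if member_id not in msa.rows:
        raise KeyError(f"{member_id} not in alignment")
    letters = []
    ok = True
    for pos, allowed in zip(anchor.positions, anchor.expected):
        col = map_reference_position(msa, anchor.reference_id, pos)
        ch = msa.rows[member_id][col - 1]
        letters.append(ch)
        if ch not in allowed:
            ok = False
    return AnchorState(member_id, anchor.anchor_id, tuple(letters), ok)
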