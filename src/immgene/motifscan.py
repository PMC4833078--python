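"""Degenerate-pattern motif matching and PSSM-based domain detection.

Degenerate motifs are exact patterns over the amino-acid alphabet in which
``X`` matches any residue — the form in which the NIM repeat
(CXPXCXXXCXNGXCXXPXXCXCXXGY) and the thioester motif (GCGEQ) are written.
Domain models are ungapped position-specific scoring matrices (log2-odds
with pseudocount smoothing) built from small reference alignments; their
score thresholds are calibrated on the training rows themselves.  The
matcher is a direct per-position set comparison, deliberately independent of
the regular-expression machinery used as an oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import MultipleAlignment, _AA_INDEX
from .io_formats import ALPHABET, AA20, ProteinRecord

#: bundled degenerate consensus for the RHIM (Imd-interacting) segment of
#: transmembrane PGRPs.  The published model is an HMM whose consensus is not
#: printed; this synthetic stand-in is a configuration default and can be
#: replaced by the user.
RHIM_CONSENSUS = "IQIGXXNXXSXE"

#: default threshold calibration: the accept threshold is the weakest
#: training row's self-score minus a margin; by default the margin scales
#: with that score (40% erosion allowed), so long domain models tolerate
#: substantial divergence while short models stay conservative
DEFAULT_PSSM_EROSION = 0.4


@dataclass(frozen=True)
class DegenerateMotif:
    """Exact pattern over the 20 amino acids plus X (X = any residue)."""

    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"motif {self.motif_id}: pattern shorter than 3")
        bad = set(self.pattern) - set(ALPHABET)
        if bad:
            raise ValueError(f"motif {self.motif_id}: illegal characters {sorted(bad)}")
        if set(self.pattern) == {"X"}:
            raise ValueError(f"motif {self.motif_id}: needs at least one fixed position")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    species: str
    protein_id: str
    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid hit span")


@dataclass(frozen=True)
class DomainHit:
    species: str
    protein_id: str
    name: str
    start: int  # 1-based inclusive
    end: int
    score: float


def compile_degenerate_motif(pattern: str, motif_id: str | None = None) -> DegenerateMotif:
    """Validate and compile a degenerate pattern string."""
    return DegenerateMotif(motif_id or pattern, pattern.upper())


def scan_motif(record: ProteinRecord, motif: DegenerateMotif) -> list[MotifHit]:
    """All (possibly overlapping) occurrences, left to right, 1-based."""
    seq = record.sequence
    pat = motif.pattern
    L = len(pat)
    fixed = [(k, ch) for k, ch in enumerate(pat) if ch != "X"]
    hits = []
    for i in range(len(seq) - L + 1):
        if all(seq[i + k] == ch for k, ch in fixed):
            hits.append(MotifHit(record.species, record.protein_id, motif.motif_id,
                                 i + 1, i + L))
    return hits


# ---------------------------------------------------------------------------
# PSSMs
# ---------------------------------------------------------------------------

@dataclass
class PSSM:
    """Ungapped log2-odds scoring matrix for one domain model.

    ``matrix`` has one row per kept alignment column and one column per
    letter of :data:`ALPHABET` (X scores 0 everywhere).  ``threshold`` is the
    accept score set at build time.
    """

    name: str
    matrix: np.ndarray
    threshold: float
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def score_window(self, window: str) -> float:
        idx = [_AA_INDEX[c] for c in window]
        return float(self.matrix[np.arange(self.length), idx].sum())


def build_pssm(msa: MultipleAlignment, pseudocount: float = 0.5,
               background: Sequence[float] | None = None,
               margin: float | None = None,
               name: str = "domain") -> PSSM:
    """Build a PSSM from a reference alignment.

    Columns with more than 50% gaps are dropped.  Scores are
    log2((count + pseudocount*bg) / (n + pseudocount) / bg) per letter;
    X always scores 0.  The threshold is the minimum score the training rows
    themselves achieve on the model, minus a margin: ``margin`` bits when
    given, else 40% of that minimum self-score (:data:`DEFAULT_PSSM_EROSION`).
    """
    if len(msa.ids) < 2:
        raise ValueError("build_pssm needs >= 2 alignment rows")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    nrows = len(msa.ids)
    rows = [msa.rows[i] for i in msa.ids]
    keep = [c for c in range(msa.ncols)
            if sum(r[c] == "-" for r in rows) <= 0.5 * nrows]
    if not keep:
        raise ValueError("all columns are gap-dominated")

    counts = np.zeros((len(keep), 20))
    for r in rows:
        for out_c, c in enumerate(keep):
            ch = r[c]
            if ch != "-" and ch != "X":
                counts[out_c, AA20.index(ch)] += 1.0

    if background is None:
        tot = counts.sum(axis=0)
        if tot.sum() == 0:
            raise ValueError("no residues in alignment")
        bg = (tot + 1e-9)
        bg = bg / bg.sum()
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    col_n = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * bg) / (col_n + pseudocount)
    scores20 = np.log2(freqs / bg)
    matrix = np.zeros((len(keep), len(ALPHABET)))
    matrix[:, :20] = scores20  # X column stays 0

    pssm = PSSM(name=name, matrix=matrix, threshold=-math.inf, background=bg)
    self_scores = []
    for i in msa.ids:
        seq = msa.degapped(i)
        hits = _window_scores(seq, matrix)
        if hits.size:
            self_scores.append(float(hits.max()))
    if not self_scores:
        raise ValueError("training rows shorter than model")
    min_self = min(self_scores)
    if margin is None:
        margin = DEFAULT_PSSM_EROSION * abs(min_self)
    pssm.threshold = min_self - margin
    return pssm


def _window_scores(seq: str, matrix: np.ndarray) -> np.ndarray:
    """Score of every window placement of the model along the sequence."""
    L = matrix.shape[0]
    n = len(seq)
    if n < L:
        return np.empty(0)
    enc = np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=n)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    return matrix[np.arange(L), windows].sum(axis=1)


def scan_pssm(record: ProteinRecord, pssm: PSSM) -> list[DomainHit]:
    """All window placements scoring >= threshold, reduced greedily to
    non-overlapping hits by descending score (ties to the leftmost)."""
    scores = _window_scores(record.sequence, pssm.matrix)
    L = pssm.length
    cand = [(float(s), i) for i, s in enumerate(scores) if s >= pssm.threshold]
    cand.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[tuple[float, int]] = []
    covered: list[tuple[int, int]] = []
    for s, i in cand:
        span = (i, i + L)
        if all(span[1] <= a or span[0] >= b for a, b in covered):
            chosen.append((s, i))
            covered.append(span)
    chosen.sort(key=lambda t: t[1])
    return [DomainHit(record.species, record.protein_id, pssm.name,
                      i + 1, i + L, s) for s, i in chosen]


def scan_rhim(record: ProteinRecord,
              motif: DegenerateMotif | None = None) -> tuple[bool, list[MotifHit]]:
    """Presence/absence of the RHIM segment (bundled degenerate consensus by
    default; replaceable by the caller)."""
    if motif is None:
        motif = compile_degenerate_motif(RHIM_CONSENSUS, "RHIM")
    hits = scan_motif(record, motif)
    return bool(hits), hits


# ---------------------------------------------------------------------------
# Tabular IO (domain-table layout compatible with search-tool output)
# ---------------------------------------------------------------------------

DOMAIN_TABLE_HEADER = "species\tprotein_id\tdomain\tstart\tend\tscore"


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    rows = sorted(hits, key=lambda h: (h.species, h.protein_id, h.start, h.name))
    with open(path, "w") as fh:
        fh.write(DOMAIN_TABLE_HEADER + "\n")
        for h in rows:
            fh.write(f"{h.species}\t{h.protein_id}\t{h.name}\t{h.start}\t"
                     f"{h.end}\t{h.score:.3f}\n")


def read_domain_hits(path) -> list[DomainHit]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != DOMAIN_TABLE_HEADER:
            raise ValueError(f"{path}: unexpected domain-table header")
        for line in fh:
            sp, pid, dom, s, e, sc = line.rstrip("\n").split("\t")
            out.append(DomainHit(sp, pid, dom, int(s), int(e), float(sc)))
    return out
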