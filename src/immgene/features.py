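"""Built-in structural-feature heuristics: transmembrane helices, signal
peptides, leucine-rich repeats, cysteine clusters, and the derived cellular
localization.

These are deliberately simple, fully specified stand-ins for the dedicated
predictors a large-scale study would use (an HMM-based TM topology
predictor, a neural-network signal-peptide predictor, an LRR template
library).  On sequences with cleanly implanted features they are exact; on
real proteomes they trade sensitivity for transparency, which the methods
note discusses.

All reported coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ProteinRecord

#: Kyte–Doolittle hydropathy scale (X treated as neutral 0).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

#: LRR core consensus LxxLxLxxNxL and its default residue classes.
LRR_L_CLASS = frozenset("LIVF")
LRR_N_CLASS = frozenset("NCTS")
LRR_PATTERN = "LxxLxLxxNxL"

TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MIN_LEN = 15
SIGNAL_SEARCH_LEN = 30
SIGNAL_CORE_LEN = 8
MEMBRANE_PROXIMAL = 35  # a TM starting beyond this is a true anchor, not a signal
JUXTAMEMBRANE_DIST = 30


@dataclass(frozen=True)
class TMSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CysCluster:
    start: int  # 1-based inclusive
    end: int
    cys_count: int
    juxtamembrane: bool


@dataclass
class StructureProfile:
    """All structural features of one protein plus the derived localization."""

    species: str
    protein_id: str
    signal_peptide: bool
    tm_segments: list[TMSegment]
    lrrs: list[tuple[int, int]]
    cys_clusters: list[CysCluster]
    localization: str  # secreted | transmembrane | intracellular


def _hydropathy(seq: str) -> np.ndarray:
    return np.fromiter((KYTE_DOOLITTLE[c] for c in seq), dtype=float, count=len(seq))


def predict_tm(record: ProteinRecord, window: int = TM_WINDOW,
               threshold: float = TM_THRESHOLD) -> list[TMSegment]:
    """Transmembrane helix segments from sliding-window mean hydropathy.

    Windows whose Kyte–Doolittle mean exceeds ``threshold`` are merged into
    maximal covered spans; span ends are trimmed inward over hydrophilic
    residues (KD < 0) and spans shorter than 15 residues are dropped.
    """
    seq = record.sequence
    if len(seq) < window:
        return []
    vals = _hydropathy(seq)
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    above = means > threshold
    segments: list[TMSegment] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        lo, hi = i, j + window - 1  # covered residue span, 0-based inclusive
        while lo <= hi and vals[lo] < 0:
            lo += 1
        while hi >= lo and vals[hi] < 0:
            hi -= 1
        if hi - lo + 1 >= TM_MIN_LEN:
            segments.append(TMSegment(lo + 1, hi + 1,
                                      float(vals[lo:hi + 1].mean())))
        i = j + 1
    return segments


def predict_signal_peptide(record: ProteinRecord, core_len: int = SIGNAL_CORE_LEN,
                           threshold: float = TM_THRESHOLD,
                           search_len: int = SIGNAL_SEARCH_LEN) -> bool:
    """Heuristic signal-peptide call.

    True iff the first ``search_len`` residues contain a hydrophobic core of
    at least ``core_len`` residues (window mean KD above ``threshold``) and
    the N-terminus does not start a transmembrane segment reaching past
    residue 35 (which would be a signal anchor / type-II membrane protein).
    """
    seq = record.sequence
    if len(seq) < 25:
        return False
    head = _hydropathy(seq[:min(search_len, len(seq))])
    if len(head) < core_len:
        return False
    means = np.convolve(head, np.ones(core_len) / core_len, mode="valid")
    if not (means > threshold).any():
        return False
    for seg in predict_tm(record):
        if seg.start <= MEMBRANE_PROXIMAL < seg.end:
            return False
    return True


def localize(signal_peptide: bool, tm_segments: list[TMSegment]) -> str:
    """Derived cellular localization.

    A transmembrane segment outside the N-terminal signal region (start
    beyond residue 35) dominates; otherwise a signal peptide implies a
    secreted protein; otherwise the protein is predicted intracellular.
    """
    if any(seg.start > MEMBRANE_PROXIMAL for seg in tm_segments):
        return "transmembrane"
    if signal_peptide:
        return "secreted"
    return "intracellular"


def find_lrrs(record: ProteinRecord, l_class: frozenset[str] = LRR_L_CLASS,
              n_class: frozenset[str] = LRR_N_CLASS,
              merge_gap: int = 5) -> list[tuple[int, int]]:
    """Matches of the degenerate LRR core consensus LxxLxLxxNxL.

    L positions accept {L,I,V,F}, the N position {N,C,T,S}, x anything.
    Matches closer than ``merge_gap`` residues are merged into one span.
    Spans are 1-based inclusive, in sequence order.
    """
    seq = record.sequence
    L = len(LRR_PATTERN)
    raw: list[tuple[int, int]] = []
    for i in range(len(seq) - L + 1):
        w = seq[i:i + L]
        if (w[0] in l_class and w[3] in l_class and w[5] in l_class
                and w[8] in n_class and w[10] in l_class):
            raw.append((i + 1, i + L))
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def find_cys_clusters(record: ProteinRecord, region: tuple[int, int] | None = None,
                      window: int = 12, min_cys: int = 2,
                      tm_start: int | None = None) -> list[CysCluster]:
    """Cysteine clusters: greedy left-to-right maximal windows of at most
    ``window`` residues holding at least ``min_cys`` cysteines.

    ``region`` restricts the scan (1-based inclusive; default whole
    sequence).  A cluster is flagged juxtamembrane when its end lies within
    30 residues of ``tm_start`` (the 1-based start of the first TM helix).
    """
    seq = record.sequence
    lo, hi = (1, len(seq)) if region is None else region
    if not (1 <= lo <= hi <= len(seq)):
        raise ValueError("region outside sequence")
    cys = [i for i in range(lo - 1, hi) if seq[i] == "C"]
    clusters: list[CysCluster] = []
    k = 0
    while k < len(cys):
        start = cys[k]
        group = [c for c in cys[k:] if c <= start + window - 1]
        if len(group) >= min_cys:
            end = group[-1]
            # "adjacent to the membrane": cluster end within 30 residues of
            # the TM start (small overlap tolerated — hydropathy-predicted
            # helix boundaries are approximate)
            juxta = (tm_start is not None
                     and tm_start - (end + 1) <= JUXTAMEMBRANE_DIST)
            clusters.append(CysCluster(start + 1, end + 1, len(group), juxta))
            k += len(group)
        else:
            k += 1
    return clusters


def structure_profile(record: ProteinRecord) -> StructureProfile:
    """Run every feature predictor and derive the localization."""
    tm = predict_tm(record)
    signal = predict_signal_peptide(record)
    loc = localize(signal, tm)
    # ectodomain = region N-terminal of the first membrane-anchoring TM;
    # the scan region reaches a few residues into the predicted helix, whose
    # hydropathy-based start may undershoot the true membrane boundary
    anchor_tms = [seg for seg in tm if seg.start > MEMBRANE_PROXIMAL]
    if anchor_tms:
        tm_start = anchor_tms[0].start
        ecto = (1, min(len(record.sequence), tm_start + 11))
    else:
        ecto = (1, len(record.sequence))
        tm_start = None
    clusters = find_cys_clusters(record, region=ecto, tm_start=tm_start) \
        if ecto[1] >= 1 else []
    return StructureProfile(
        species=record.species,
        protein_id=record.protein_id,
        signal_peptide=signal,
        tm_segments=tm,
        lrrs=find_lrrs(record),
        cys_clusters=clusters,
        localization=loc,
    )


FEATURE_TABLE_HEADER = ("species\tprotein_id\tsignal_peptide\ttm_segments\t"
                        "lrrs\tcys_clusters\tlocalization")


def write_feature_table(profiles, path) -> None:
    """Feature spans as a TSV (1-based inclusive span lists)."""
    rows = sorted(profiles, key=lambda p: (p.species, p.protein_id))
    with open(path, "w") as fh:
        fh.write(FEATURE_TABLE_HEADER + "\n")
        for p in rows:
            tm = ",".join(f"{s.start}-{s.end}" for s in p.tm_segments) or "."
            lrr = ",".join(f"{s}-{e}" for s, e in p.lrrs) or "."
            cc = ",".join(f"{c.start}-{c.end}" for c in p.cys_clusters) or "."
            fh.write(f"{p.species}\t{p.protein_id}\t{int(p.signal_peptide)}\t"
                     f"{tm}\t{lrr}\t{cc}\t{p.localization}\n")
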