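"""Generator of multi-species synthetic proteomes with full ground truth.

Families of immune genes evolve along a species tree by a birth–death
(duplication/loss) process; each surviving gene copy is a protein built from
a family-specific domain grammar — signal peptide, diagnostic domain blocks,
transmembrane helix, cysteine clusters, leucine-rich repeats, degenerate
motifs, and functional residue anchors whose state (intact vs ablated) is
drawn per copy.  Background proteins carry no planted features.  Everything
the annotation pipeline consumes (proteome FASTA files, a labeled query set
for the reference species, the family-rule configuration, domain training
alignments) is emitted alongside a machine-readable truth table, so every
pipeline stage can be scored against known truth.

All sequences here are synthetic; domain "consensus" blocks are fixed random
strings, not biological sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import phylo
from .io_formats import (AA20, FamilyRule, ProteinRecord, RuleSet,
                         write_fasta, write_ruleset)
from .motifscan import RHIM_CONSENSUS

#: fixed documented background amino-acid frequency table (approximately the
#: composition of globular proteins), order matching AA20
AA_FREQS = {
    "A": 0.078, "C": 0.019, "D": 0.053, "E": 0.063, "F": 0.039, "G": 0.072,
    "H": 0.022, "I": 0.053, "K": 0.059, "L": 0.091, "M": 0.022, "N": 0.045,
    "P": 0.052, "Q": 0.043, "R": 0.051, "S": 0.068, "T": 0.059, "V": 0.066,
    "W": 0.014, "Y": 0.032,
}

_BG_LETTERS = np.array(list(AA_FREQS))
_BG_WEIGHTS = np.array(list(AA_FREQS.values()))
_BG_WEIGHTS = _BG_WEIGHTS / _BG_WEIGHTS.sum()

#: linkers exclude cysteine (cluster truth stays exact) and are re-drawn if
#: they contain an 8-residue hydrophobic stretch (so they can never fake a
#: signal peptide or membrane helix)
_LINKER_LETTERS = np.array([a for a in AA_FREQS if a != "C"])
_LINKER_WEIGHTS = np.array([AA_FREQS[a] for a in _LINKER_LETTERS])
_LINKER_WEIGHTS = _LINKER_WEIGHTS / _LINKER_WEIGHTS.sum()

_KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
       "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
       "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
       "Y": -1.3, "V": 4.2, "X": 0.0}

NIM_PATTERN = "CXPXCXXXCXNGXCXXPXXCXCXXGY"
THIOESTER = "GCGEQ"

SIGNAL_ELEMENT = "MKRLLVLLALLVLSAQA"          # tripartite signal peptide
TM_ELEMENT = "LLIVLFALLIVALLIVFALLIVALL"      # 25-residue hydrophobic helix
CYS_CLUSTER_ELEMENT = "CPKC"
LRR_UNIT = "PA" + "LRALDLSNNQL" + "TGSQPDSWGKA"  # one 24-residue repeat

_CONSENSUS_SEED = 910203  # fixed: domain blocks are package constants

FAMILIES = ("PGRP", "BGRP", "TEP", "TLR", "Relish", "Nimrod")

#: domain-local 1-based anchor positions
PGRP_TRIAD_REL = (45, 88, 96)       # C, H, H (zinc-binding amidase triad)
GH16_GLU_REL = (138, 143)           # E, E; abs 188/193 in the reference layout
TED_MOTIF_REL = 120                 # GCGEQ start within the TED block


def _rand_letters(rng: np.random.Generator, n: int, letters=_BG_LETTERS,
                  weights=_BG_WEIGHTS) -> str:
    return "".join(rng.choice(letters, size=n, p=weights))


def _linker(rng: np.random.Generator, n: int) -> str:
    """Hydrophilic-safe linker: no 8-window with mean hydropathy > 1.2."""
    while True:
        s = _rand_letters(rng, n, _LINKER_LETTERS, _LINKER_WEIGHTS)
        if n < 8:
            return s
        vals = np.array([_KD[c] for c in s])
        means = np.convolve(vals, np.ones(8) / 8, mode="valid")
        if (means <= 1.2).all():
            return s


def _set_positions(seq: str, pos_rel1: tuple[int, ...], letters: str) -> str:
    out = list(seq)
    for p, ch in zip(pos_rel1, letters):
        out[p - 1] = ch
    return "".join(out)


def _domain_consensi() -> dict[str, str]:
    """Fixed synthetic domain consensus blocks (module constants in effect)."""
    rng = np.random.default_rng(_CONSENSUS_SEED)
    cons: dict[str, str] = {}
    cons["PGRP"] = _set_positions(_linker(rng, 160), PGRP_TRIAD_REL, "CHH")
    cons["GH16"] = _set_positions(_linker(rng, 220), GH16_GLU_REL, "EE")
    ted = _linker(rng, 300)
    ted = ted[:TED_MOTIF_REL - 1] + THIOESTER + ted[TED_MOTIF_REL - 1 + 5:]
    cons["TED"] = ted
    cons["TIR"] = _linker(rng, 140)
    cons["RHD"] = _linker(rng, 180)
    cons["ANK"] = _linker(rng, 33)
    assert cons["TED"].count(THIOESTER) == 1
    return cons


_CONSENSI = _domain_consensi()


def realize_degenerate(pattern: str, rng: np.random.Generator) -> str:
    """Instantiate a degenerate pattern, drawing X positions from the linker
    composition (cysteine-free, so planted cysteines stay exact)."""
    return "".join(
        ch if ch != "X" else str(rng.choice(_LINKER_LETTERS, p=_LINKER_WEIGHTS))
        for ch in pattern)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    name: str
    ancestral_copies: int
    duplication_rate: float  # events per unit branch length
    loss_rate: float

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")


DEFAULT_FAMILY_SPECS = (
    FamilySpec("PGRP", 3, 0.8, 0.4),
    FamilySpec("BGRP", 2, 0.8, 0.4),
    FamilySpec("TEP", 2, 0.8, 0.4),
    FamilySpec("TLR", 3, 0.8, 0.4),
    FamilySpec("Relish", 1, 0.1, 0.05),
    FamilySpec("Nimrod", 2, 0.8, 0.4),
)

#: per-copy functional-state frequencies (study conditions, fixed)
STATE_PROBS = {
    "pgrp_catalytic": 0.6,
    "pgrp_variant": (("secreted", 0.4), ("intracellular", 0.4),
                     ("transmembrane", 0.2)),
    "gh16_catalytic": 0.7,
    "tep_motif": 0.6,
    "tlr_scc": 0.5,
    "relish_ankyrin": 0.75,
}


@dataclass
class GeneratorConfig:
    species_tree: str            # newick, branch lengths in substitutions/site
    reference_species: str
    families: tuple[FamilySpec, ...] = DEFAULT_FAMILY_SPECS
    background_per_species: int = 200
    background_length: tuple[int, int] = (120, 400)
    divergence: float = 0.0      # substitution multiplier along the tree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


def default_config(seed: int = 0, divergence: float = 0.0,
                   n_species: int = 4,
                   background_per_species: int = 200) -> GeneratorConfig:
    """The default study conditions: 4 species (one reference), 6 families,
    200 background proteins per species, no substitution noise.  Divergence
    presets: 0.05 for recoverable fixtures, 0.4 for degraded-input tests."""
    trees = {
        2: "(sp1:0.25,refsp:0.25);",
        3: "((sp1:0.25,sp2:0.25):0.25,refsp:0.5);",
        4: "((sp1:0.25,sp2:0.25):0.25,(sp3:0.25,refsp:0.25):0.25);",
    }
    if n_species not in trees:
        raise ValueError("n_species must be 2, 3, or 4")
    return GeneratorConfig(species_tree=trees[n_species],
                           reference_species="refsp",
                           background_per_species=background_per_species,
                           divergence=divergence, seed=seed)


# ---------------------------------------------------------------------------
# Birth–death gene-family evolution
# ---------------------------------------------------------------------------

def _simulate_lineage(t: float, rate_b: float, rate_d: float,
                      rng: np.random.Generator) -> int:
    """Surviving descendant count of one lineage after time t."""
    total = rate_b + rate_d
    if total == 0:
        return 1
    tau = rng.exponential(1.0 / total)
    if tau >= t:
        return 1
    if rng.random() < rate_b / total:
        return (_simulate_lineage(t - tau, rate_b, rate_d, rng)
                + _simulate_lineage(t - tau, rate_b, rate_d, rng))
    return 0


def evolve_family(species_tree: TreeNode, spec: FamilySpec,
                  rng: np.random.Generator) -> dict[str, list[int]]:
    """Duplication/loss along the species tree.

    Returns, per tip species, the list of ancestral-copy tags (orthogroup
    indices) of its surviving gene copies; duplicated copies repeat a tag.
    """
    def descend(node: TreeNode, copies: list[int]) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        if node.is_tip():
            out[node.name] = list(copies)
            return out
        for child in node.children:
            t = child.length or 0.0
            surviving: list[int] = []
            for og in copies:
                k = _simulate_lineage(t, spec.duplication_rate * 1.0,
                                      spec.loss_rate * 1.0, rng) if t > 0 else 1
                surviving.extend([og] * k)
            out.update(descend(child, surviving))
        return out

    root_copies = list(range(spec.ancestral_copies))
    return descend(species_tree, root_copies)


def mutate(sequence: str, rate: float, rng: np.random.Generator,
           protected_positions: frozenset[int] = frozenset()) -> str:
    """i.i.d. substitution: each unprotected position is replaced with
    probability ``rate`` by a uniform draw from the other 19 residues.
    ``protected_positions`` are 0-based."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return sequence
    out = list(sequence)
    hits = rng.random(len(out)) < rate
    for i in np.flatnonzero(hits):
        if int(i) in protected_positions:
            continue
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

@dataclass
class BuiltProtein:
    sequence: str
    family: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based
    motifs: list[tuple[str, int, int]] = field(default_factory=list)
    tm: list[tuple[int, int]] = field(default_factory=list)
    clusters: list[tuple[int, int]] = field(default_factory=list)
    signal: bool = False
    localization: str = "intracellular"
    catalytic: str = "."   # yes | no | .
    thioester: str = "."
    tlr_class: str = "."
    rhim: str = "."
    ankyrin: str = "."
    anchor_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    protected: set[int] = field(default_factory=set)  # 0-based


class _Assembler:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0  # residues so far

    def add(self, seq: str) -> tuple[int, int]:
        """Append; returns the 1-based inclusive span."""
        start = self.pos + 1
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _ablate(seq_rel: str, rel_positions: tuple[int, ...], replacements: str,
            which: list[int]) -> str:
    out = list(seq_rel)
    for k in which:
        out[rel_positions[k] - 1] = replacements[k]
    return "".join(out)


def build_protein(family: str, rng: np.random.Generator,
                  canonical: bool = False) -> BuiltProtein:
    """Assemble one gene copy from its family grammar.

    ``canonical`` forces the annotated-exemplar state (intact residues,
    motif present, reference layout) used for the reference species' first
    copy of each family.

    The builder rejection-samples: random linkers are re-drawn when element
    boundaries happen to form an unintended signal-peptide-like or
    membrane-helix-like hydrophobic stretch, so the planted localization is
    always well-defined (background emulation stays feature-free).
    """
    for _ in range(50):
        bp = _assemble(family, rng, canonical)
        if _nterm_clean(bp):
            return bp
    raise RuntimeError(f"could not assemble a clean {family} protein")


def _nterm_clean(bp: BuiltProtein) -> bool:
    """No unintended membrane anchor or signal core (hydropathy check using
    the same definitions as the feature module)."""
    from . import features as F

    rec = ProteinRecord("x", "x", bp.sequence)
    anchor = [s for s in F.predict_tm(rec) if s.start > F.MEMBRANE_PROXIMAL]
    if bp.localization == "transmembrane":
        # every membrane-anchoring prediction must belong to a planted helix
        return bool(anchor) and all(
            any(s.start <= te and ts - 15 <= s.start for ts, te in bp.tm)
            for s in anchor)
    if anchor:
        return False
    return F.predict_signal_peptide(rec) == bp.signal


def _assemble(family: str, rng: np.random.Generator,
              canonical: bool) -> BuiltProtein:
    b = _Assembler()
    out = BuiltProtein(sequence="", family=family)

    def mark_protected(span: tuple[int, int], rel_offsets=None) -> None:
        s, e = span
        if rel_offsets is None:
            out.protected.update(range(s - 1, e))
        else:
            out.protected.update(s - 1 + r for r in rel_offsets)

    if family == "PGRP":
        variant = "secreted" if canonical else _choice_weighted(
            rng, STATE_PROBS["pgrp_variant"])
        catalytic = True if canonical else rng.random() < STATE_PROBS["pgrp_catalytic"]
        dom = _CONSENSI["PGRP"]
        if not catalytic:
            which = _nonempty_subset(rng, 3)
            dom = _ablate(dom, PGRP_TRIAD_REL, "SYY", which)
        if variant == "secreted":
            b.add(SIGNAL_ELEMENT)
            out.signal = True
            b.add(_linker(rng, 15))
            span = b.add(dom)
            b.add(_linker(rng, 20))
            out.localization = "secreted"
        elif variant == "intracellular":
            b.add("M")
            b.add(_linker(rng, 18))
            span = b.add(dom)
            b.add(_linker(rng, 20))
            out.localization = "intracellular"
        else:  # transmembrane, with an intracellular RHIM segment
            b.add("M")
            b.add(_linker(rng, 8))
            rhim = realize_degenerate(RHIM_CONSENSUS, rng)
            rspan = b.add(rhim)
            out.motifs.append(("RHIM", *rspan))
            mark_protected(rspan, [k for k, c in enumerate(RHIM_CONSENSUS) if c != "X"])
            b.add(_linker(rng, 30))
            tspan = b.add(TM_ELEMENT)
            out.tm.append(tspan)
            b.add(_linker(rng, 8))
            span = b.add(dom)
            b.add(_linker(rng, 10))
            out.localization = "transmembrane"
            out.rhim = "yes"
        out.domains.append(("PGRP", *span))
        triad = tuple(span[0] - 1 + p for p in PGRP_TRIAD_REL)
        out.anchor_positions["PGRP_triad"] = triad
        mark_protected(span, [p - 1 for p in PGRP_TRIAD_REL])
        out.catalytic = "yes" if catalytic else "no"
        if out.rhim == "." and variant == "transmembrane":
            out.rhim = "yes"
        elif variant != "transmembrane":
            out.rhim = "no"

    elif family == "BGRP":
        catalytic = True if canonical else rng.random() < STATE_PROBS["gh16_catalytic"]
        dom = _CONSENSI["GH16"]
        if not catalytic:
            which = _nonempty_subset(rng, 2)
            dom = _ablate(dom, GH16_GLU_REL, "QQ", which)
        b.add(SIGNAL_ELEMENT)
        out.signal = True
        b.add(_linker(rng, 33))
        span = b.add(dom)
        b.add(_linker(rng, 20))
        out.localization = "secreted"
        out.domains.append(("GH16", *span))
        out.anchor_positions["GH16_glu_pair"] = tuple(
            span[0] - 1 + p for p in GH16_GLU_REL)
        mark_protected(span, [p - 1 for p in GH16_GLU_REL])
        out.catalytic = "yes" if catalytic else "no"

    elif family == "TEP":
        motif = True if canonical else rng.random() < STATE_PROBS["tep_motif"]
        dom = _CONSENSI["TED"]
        if not motif:
            # ablate the critical cysteine: GCGEQ -> GAGEQ
            i = TED_MOTIF_REL - 1
            dom = dom[:i + 1] + "A" + dom[i + 2:]
        b.add(SIGNAL_ELEMENT)
        out.signal = True
        b.add(_linker(rng, 25))
        span = b.add(dom)
        b.add(_linker(rng, 25))
        out.localization = "secreted"
        out.domains.append(("TED", *span))
        mstart = span[0] + TED_MOTIF_REL - 1
        if motif:
            out.motifs.append(("GCGEQ", mstart, mstart + 4))
        mark_protected((mstart, mstart + 4))
        out.thioester = "yes" if motif else "no"

    elif family == "TLR":
        scc = rng.random() < STATE_PROBS["tlr_scc"]
        b.add(SIGNAL_ELEMENT)
        out.signal = True
        if not scc:
            b.add(_linker(rng, 6))
            cspan = b.add(CYS_CLUSTER_ELEMENT)
            out.clusters.append(cspan)
            mark_protected(cspan)
        b.add(_linker(rng, 10))
        for _ in range(6):
            s, e = b.add(LRR_UNIT)
            out.motifs.append(("LRR", s + 2, s + 12))  # the 11-residue core
            mark_protected((s, e), range(2, 13))
        b.add(_linker(rng, 6))
        cspan = b.add(CYS_CLUSTER_ELEMENT)
        out.clusters.append(cspan)
        mark_protected(cspan)
        b.add(_linker(rng, 8))
        tspan = b.add(TM_ELEMENT)
        out.tm.append(tspan)
        mark_protected(tspan)
        b.add(_linker(rng, 5))
        span = b.add(_CONSENSI["TIR"])
        out.domains.append(("TIR", *span))
        b.add(_linker(rng, 10))
        out.localization = "transmembrane"
        out.tlr_class = "scc" if scc else "mcc"

    elif family == "Relish":
        ankyrin = True if canonical else rng.random() < STATE_PROBS["relish_ankyrin"]
        b.add("M")
        b.add(_linker(rng, 12))
        span = b.add(_CONSENSI["RHD"])
        out.domains.append(("RHD", *span))
        b.add(_linker(rng, 15))
        if ankyrin:
            for _ in range(4):
                aspan = b.add(_CONSENSI["ANK"])
                out.domains.append(("ANK", *aspan))
        b.add(_linker(rng, 10))
        out.localization = "intracellular"
        out.ankyrin = "yes" if ankyrin else "no"

    elif family == "Nimrod":
        b.add(SIGNAL_ELEMENT)
        out.signal = True
        b.add(_linker(rng, 10))
        for k in range(3):
            nim = realize_degenerate(NIM_PATTERN, rng)
            nspan = b.add(nim)
            out.motifs.append(("NIM", *nspan))
            mark_protected(nspan, [i for i, c in enumerate(NIM_PATTERN) if c != "X"])
            if k < 2:
                b.add(_linker(rng, 8))
        b.add(_linker(rng, 12))
        out.localization = "secreted"

    else:
        raise ValueError(f"unknown family {family!r}")

    # signal element residues must survive mutation for the localization
    # truth to stay exact at nonzero divergence
    if out.signal:
        out.protected.update(range(len(SIGNAL_ELEMENT)))
    for s, e in out.tm:
        out.protected.update(range(s - 1, e))
    out.sequence = b.sequence
    return out


def _choice_weighted(rng: np.random.Generator, options) -> str:
    names = [n for n, _ in options]
    probs = np.array([p for _, p in options])
    return str(rng.choice(names, p=probs / probs.sum()))


def _nonempty_subset(rng: np.random.Generator, n: int) -> list[int]:
    while True:
        picks = [k for k in range(n) if rng.random() < 0.5]
        if picks:
            return picks


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["species", "protein_id", "family", "orthogroup",
                 "localization", "catalytic", "thioester", "tlr_class",
                 "rhim", "ankyrin", "features"]


def _feature_string(bp: BuiltProtein) -> str:
    items = [f"{n}:{s}-{e}" for n, s, e in bp.domains]
    items += [f"{n}:{s}-{e}" for n, s, e in bp.motifs]
    items += [f"TM:{s}-{e}" for s, e in bp.tm]
    items += [f"CYS:{s}-{e}" for s, e in bp.clusters]
    return ";".join(items) if items else "."


def default_ruleset(anchors: dict[str, dict]) -> RuleSet:
    """The bundled family rules; anchors are filled in from the emitted
    reference exemplars."""
    from .align import ResidueAnchor

    families = {
        "PGRP": FamilyRule("PGRP", required_domains=(("PGRP", 1),),
                           residue_anchors=("PGRP_triad",)),
        "BGRP": FamilyRule("BGRP", required_domains=(("GH16", 1),),
                           residue_anchors=("GH16_glu_pair",)),
        "TEP": FamilyRule("TEP", required_domains=(("TED", 1),)),
        "TLR": FamilyRule("TLR", required_domains=(("LRR", 1), ("TIR", 1), ("TM", 1)),
                          localization_expected="transmembrane"),
        "Relish": FamilyRule("Relish", required_domains=(("RHD", 1),)),
        "Nimrod": FamilyRule("Nimrod", required_motifs=("NIM",)),
    }
    motifs = {"NIM": NIM_PATTERN, "GCGEQ": THIOESTER, "RHIM": RHIM_CONSENSUS}
    anchor_objs = {
        aid: ResidueAnchor(aid, spec["reference"],
                           tuple(spec["positions"]),
                           tuple(frozenset(e) for e in spec["expected"]))
        for aid, spec in anchors.items()
    }
    return RuleSet(families=families, motifs=motifs, anchors=anchor_objs)


@dataclass
class Dataset:
    """In-memory emitted dataset plus the paths written (if any)."""

    config: GeneratorConfig
    proteomes: dict[str, list[ProteinRecord]]
    query_families: dict[str, str]   # reference protein id -> family
    ruleset: RuleSet
    domain_alignments: dict[str, list[tuple[str, str]]]  # name -> [(id, row)]
    truth: pd.DataFrame
    outdir: Path | None = None


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Build the full dataset in memory, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    tree = phylo.read_newick(config.species_tree)
    species = sorted(t.name for t in tree.tips())
    if config.reference_species not in species:
        raise ValueError("reference species must be a tip of the species tree")
    depth = {t.name: sum((a.length or 0.0) for a in t.ancestors() if a.length)
             + (t.length or 0.0) for t in tree.tips()}

    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in species}
    query_families: dict[str, str] = {}
    truth_rows: list[list] = []
    anchors_cfg: dict[str, dict] = {}

    for spec in sorted(config.families, key=lambda s: s.name):
        tips = evolve_family(tree, spec, rng)
        # the reference species is the annotated query source: guarantee a copy
        ref = config.reference_species
        if not tips.get(ref):
            tips[ref] = [0]
        for sp in species:
            for idx, og in enumerate(tips.get(sp, [])):
                canonical = (sp == ref and idx == 0)
                bp = build_protein(spec.name, rng, canonical=canonical)
                rate = config.divergence * depth[sp]
                seq = mutate(bp.sequence, min(rate, 1.0), rng,
                             frozenset(bp.protected))
                pid = f"{spec.name}_og{og}_c{idx}"
                proteomes[sp].append(ProteinRecord(sp, pid, seq))
                truth_rows.append([sp, pid, spec.name, f"{spec.name}.og{og}",
                                   bp.localization, bp.catalytic, bp.thioester,
                                   bp.tlr_class, bp.rhim, bp.ankyrin,
                                   _feature_string(bp)])
                if sp == ref:
                    query_families[pid] = spec.name
                if canonical and spec.name == "PGRP":
                    anchors_cfg["PGRP_triad"] = {
                        "reference": pid,
                        "positions": list(bp.anchor_positions["PGRP_triad"]),
                        "expected": ["C", "H", "H"],
                    }
                if canonical and spec.name == "BGRP":
                    anchors_cfg["GH16_glu_pair"] = {
                        "reference": pid,
                        "positions": list(bp.anchor_positions["GH16_glu_pair"]),
                        "expected": ["E", "E"],
                    }

    # background proteins
    lo, hi = config.background_length
    for sp in species:
        for k in range(config.background_per_species):
            n = int(rng.integers(lo, hi + 1))
            seq = _rand_letters(rng, n)
            pid = f"bg{k:04d}"
            proteomes[sp].append(ProteinRecord(sp, pid, seq))
            truth_rows.append([sp, pid, "background", ".", ".", ".", ".", ".",
                               ".", ".", "."])

    # domain training alignments (external-reference stand-ins, ungapped)
    domain_alignments: dict[str, list[tuple[str, str]]] = {}
    for name in ("PGRP", "GH16", "TED", "TIR", "RHD", "ANK"):
        cons = _CONSENSI[name]
        protected: frozenset[int] = frozenset()
        if name == "PGRP":
            protected = frozenset(p - 1 for p in PGRP_TRIAD_REL)
        elif name == "GH16":
            protected = frozenset(p - 1 for p in GH16_GLU_REL)
        elif name == "TED":
            protected = frozenset(range(TED_MOTIF_REL - 1, TED_MOTIF_REL + 4))
        rows = [(f"{name}_train0", cons)]
        for k in range(1, 8):
            rows.append((f"{name}_train{k}",
                         mutate(cons, 0.07, rng, protected)))
        domain_alignments[name] = rows
    nim_fixed = frozenset(i for i, c in enumerate(NIM_PATTERN) if c != "X")
    nim_rows = []
    for k in range(16):
        inst = realize_degenerate(NIM_PATTERN, rng)
        nim_rows.append((f"NIM_train{k}", mutate(inst, 0.07, rng, nim_fixed)))
    domain_alignments["NIM"] = nim_rows

    ruleset = default_ruleset(anchors_cfg)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["species", "protein_id"], ignore_index=True)
    return Dataset(config=config, proteomes=proteomes,
                   query_families=query_families, ruleset=ruleset,
                   domain_alignments=domain_alignments, truth=truth)


def emit_dataset(config: GeneratorConfig, outdir) -> Dataset:
    """Generate and write the dataset to ``outdir``; byte-deterministic for a
    fixed seed."""
    ds = generate_dataset(config)
    outdir = Path(outdir)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    (outdir / "domain_alignments").mkdir(exist_ok=True)
    for sp in sorted(ds.proteomes):
        recs = sorted(ds.proteomes[sp], key=lambda r: r.protein_id)
        write_fasta(recs, outdir / "proteomes" / f"{sp}.fasta")
    ref = config.reference_species
    qrecs = sorted((r for r in ds.proteomes[ref]
                    if r.protein_id in ds.query_families),
                   key=lambda r: r.protein_id)
    write_fasta(qrecs, outdir / "query_set.fasta",
                descriptions={r.key: f"family={ds.query_families[r.protein_id]}"
                              for r in qrecs})
    for name in sorted(ds.domain_alignments):
        with open(outdir / "domain_alignments" / f"{name}.afa", "w") as fh:
            for rid, row in ds.domain_alignments[name]:
                fh.write(f">{rid}\n{row}\n")
    write_ruleset(ds.ruleset, outdir / "rules.yaml")
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "species": sorted(ds.proteomes),
        "reference_species": ref,
        "divergence": config.divergence,
        "background_per_species": config.background_per_species,
        "families": [s.name for s in sorted(config.families, key=lambda s: s.name)],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    ds.outdir = outdir
    return ds
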