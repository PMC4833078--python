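"""Functional classification and evidence integration.

This is the decision layer: family architecture checks (required/forbidden
domains, motifs, localization), residue-anchored catalytic calls for PGRPs
(the zinc-binding Cys + His + His amidase triad) and GH16 glucanases (the
Glu active-site pair at reference positions 188/193), thioester-motif calls
for TEPs (GCGEQ and its critical cysteine), structural classes for TLRs
(single vs multiple cysteine-cluster ectodomains), NF-kB/Relish domain
architecture, the combination of all evidence sources into accepted
annotation records, and the species x family copy-number matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import (MultipleAlignment, ResidueAnchor, residue_state_at_anchor)
from .features import StructureProfile
from .io_formats import AnnotationRecord, FamilyRule, ProteinRecord
from .motifscan import DomainHit, MotifHit

#: reserved rule-domain names satisfied from structural features
STRUCTURAL_DOMAINS = ("TM", "LRR")

TRUNCATED_TLR_MIN_ECTODOMAIN = 150


@dataclass(frozen=True)
class CatalyticCall:
    species: str
    protein_id: str
    family_context: str  # "PGRP" or "GH16"
    state: str           # "catalytic" | "non-catalytic"
    letters: tuple[str, ...]

    @property
    def asterisk(self) -> bool:
        """Figure convention: activity-lost proteins are starred."""
        return self.state == "non-catalytic"


@dataclass(frozen=True)
class TEPCall:
    species: str
    protein_id: str
    thioester_motif_present: bool
    critical_cys_present: bool

    @property
    def tep_class(self) -> str:
        return "TEP" if self.thioester_motif_present else "MCR-like"


@dataclass(frozen=True)
class TLRStructureCall:
    species: str
    protein_id: str
    tlr_class: str  # scc | mcc | atypical
    cluster_count: int
    truncated: bool


# ---------------------------------------------------------------------------
# Architecture check
# ---------------------------------------------------------------------------

def check_architecture(record: ProteinRecord, rule: FamilyRule,
                       domain_hits: Sequence[DomainHit],
                       motif_hits: Sequence[MotifHit],
                       structure: StructureProfile,
                       known_domains: Iterable[str] | None = None,
                       ) -> tuple[bool, list[str]]:
    """Does the protein satisfy the family's essential-architecture rule?

    Returns (pass, reasons); ``reasons`` lists every failed clause.  The
    reserved domain names TM and LRR are counted from the structural profile.
    """
    if known_domains is not None:
        known = set(known_domains) | set(STRUCTURAL_DOMAINS)
        unknown = ({d for d, _ in rule.required_domains}
                   | set(rule.forbidden_domains)) - known
        if unknown:
            raise KeyError(f"rule {rule.family}: unknown domain names {sorted(unknown)}")
    reasons: list[str] = []
    dom_counts: dict[str, int] = {}
    for h in domain_hits:
        dom_counts[h.name] = dom_counts.get(h.name, 0) + 1
    dom_counts["TM"] = len(structure.tm_segments)
    dom_counts["LRR"] = len(structure.lrrs)
    for name, min_count in rule.required_domains:
        if dom_counts.get(name, 0) < min_count:
            reasons.append(f"{name} absent" if min_count == 1 else
                           f"{name} count {dom_counts.get(name, 0)} < {min_count}")
    for name in rule.forbidden_domains:
        if dom_counts.get(name, 0) > 0:
            reasons.append(f"forbidden domain {name} present")
    motif_names = {m.name for m in motif_hits}
    for m in rule.required_motifs:
        if m not in motif_names:
            reasons.append(f"motif {m} absent")
    if rule.localization_expected != "any" and \
            structure.localization != rule.localization_expected:
        reasons.append(f"localization {structure.localization} != "
                       f"{rule.localization_expected}")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Residue-anchored catalytic calls
# ---------------------------------------------------------------------------

def pgrp_catalytic_call(msa: MultipleAlignment, member_id: str,
                        anchor: ResidueAnchor, species: str = "") -> CatalyticCall:
    """Amidase-activity call from the zinc-binding triad.

    Catalytic iff the columns anchored at the reference's Cys/His/His triad
    all hold the expected letters; a member gapped at any anchor is
    non-catalytic with '-' reported.
    """
    state = residue_state_at_anchor(msa, member_id, anchor)
    return CatalyticCall(species, member_id, "PGRP",
                         "catalytic" if state.all_expected else "non-catalytic",
                         state.letters)


def glucanase_activity_call(msa: MultipleAlignment, member_id: str,
                            anchor: ResidueAnchor, species: str = "") -> CatalyticCall:
    """Glucanase-activity call from the conserved Glu pair (E188/E193 in the
    reference numbering); proteins missing either Glu are flagged as the
    activity-lost (asterisk) class."""
    state = residue_state_at_anchor(msa, member_id, anchor)
    return CatalyticCall(species, member_id, "GH16",
                         "catalytic" if state.all_expected else "non-catalytic",
                         state.letters)


# ---------------------------------------------------------------------------
# TEP / TLR / Relish
# ---------------------------------------------------------------------------

THIOESTER_MOTIF = "GCGEQ"
TEP_CYS_FALLBACK_WINDOW = 10


def tep_classify(record: ProteinRecord,
                 motif_region_hint: tuple[int, int] | None = None) -> TEPCall:
    """Thioester call: scan for the canonical GCGEQ motif.

    When the motif is present its cysteine is the critical cysteine.  When
    absent, the critical cysteine is sought within the expected motif region
    (``motif_region_hint``, 1-based inclusive) widened by 10 residues; with
    no hint, absence of the motif implies absence of the cysteine.
    """
    seq = record.sequence
    idx = seq.find(THIOESTER_MOTIF)
    if idx >= 0:
        return TEPCall(record.species, record.protein_id, True, True)
    if motif_region_hint is not None:
        lo = max(1, motif_region_hint[0] - TEP_CYS_FALLBACK_WINDOW)
        hi = min(len(seq), motif_region_hint[1] + TEP_CYS_FALLBACK_WINDOW)
        has_cys = "C" in seq[lo - 1:hi]
    else:
        has_cys = False
    return TEPCall(record.species, record.protein_id, False, has_cys)


def classify_tlr(structure: StructureProfile, tir_present: bool,
                 min_ectodomain: int = TRUNCATED_TLR_MIN_ECTODOMAIN,
                 ) -> TLRStructureCall:
    """Structural TLR class from ectodomain cysteine clusters.

    scc: exactly one cluster, juxtamembrane.  mcc: exactly two clusters.
    Anything else (none, one non-juxtamembrane, or more than two) is
    atypical, with the count reported.  The truncated flag marks ectodomains
    shorter than ``min_ectodomain`` residues.
    """
    if not tir_present:
        raise ValueError(f"{structure.protein_id}: no TIR domain; not a TLR")
    clusters = structure.cys_clusters
    n = len(clusters)
    if n == 1 and clusters[0].juxtamembrane:
        cls = "scc"
    elif n == 2:
        cls = "mcc"
    else:
        cls = "atypical"
    anchor_tms = [s for s in structure.tm_segments if s.start > 35]
    ecto_len = (anchor_tms[0].start - 1) if anchor_tms else 0
    return TLRStructureCall(structure.species, structure.protein_id, cls, n,
                            truncated=ecto_len < min_ectodomain)


def relish_architecture(record: ProteinRecord,
                        domain_hits: Sequence[DomainHit],
                        rhd_name: str = "RHD", ankyrin_name: str = "ANK",
                        ) -> tuple[bool, bool]:
    """NF-kB (Relish-like) architecture: Rel homology domain plus an
    ankyrin-repeat region (>= 2 ankyrin hits C-terminal of the RHD)."""
    rhd = [h for h in domain_hits if h.name == rhd_name]
    has_rhd = bool(rhd)
    has_ank_region = False
    if has_rhd:
        rhd_end = min(h.end for h in rhd)
        anks = [h for h in domain_hits
                if h.name == ankyrin_name and h.start > rhd_end]
        has_ank_region = len(anks) >= 2
    return has_rhd, has_ank_region


# ---------------------------------------------------------------------------
# Evidence integration
# ---------------------------------------------------------------------------

@dataclass
class EvidenceBundle:
    """Everything the integrator needs to decide one protein's fate."""

    rbh_partner: str | None = None          # reference protein id
    rbh_partner_family: str | None = None   # family of that partner (if query)
    orthogroup_family: str | None = None
    profile_families: set[str] = field(default_factory=set)
    domain_hits: list[DomainHit] = field(default_factory=list)
    motif_hits: list[MotifHit] = field(default_factory=list)


@dataclass
class Rejection:
    species: str
    protein_id: str
    reason: str


def integrate_evidence(record: ProteinRecord, evidence: EvidenceBundle,
                       rules: Mapping[str, FamilyRule],
                       structure: StructureProfile,
                       known_domains: Iterable[str] | None = None,
                       ) -> AnnotationRecord | Rejection | None:
    """Combine homology, clustering, and profile evidence into a family call.

    A protein is accepted iff at least one evidence source names a family,
    the family's architecture rule passes, and — when a reciprocal best
    reference hit exists — that hit is itself a member of the family's query
    set.  Proteins with evidence for several families go to the family with
    the most independent sources; ties are rejected with a reason.  Proteins
    with no family evidence return None (they are simply not candidates).
    """
    votes: dict[str, int] = {}
    if evidence.rbh_partner_family:
        votes[evidence.rbh_partner_family] = votes.get(evidence.rbh_partner_family, 0) + 1
    if evidence.orthogroup_family:
        votes[evidence.orthogroup_family] = votes.get(evidence.orthogroup_family, 0) + 1
    for fam in evidence.profile_families:
        votes[fam] = votes.get(fam, 0) + 1
    votes = {f: v for f, v in votes.items() if f in rules}
    if not votes:
        return None
    best = max(votes.values())
    top = sorted(f for f, v in votes.items() if v == best)
    if len(top) > 1:
        return Rejection(record.species, record.protein_id,
                         f"ambiguous family evidence: {','.join(top)}")
    family = top[0]
    rule = rules[family]
    ok, reasons = check_architecture(record, rule, evidence.domain_hits,
                                     evidence.motif_hits, structure,
                                     known_domains=known_domains)
    if not ok:
        return Rejection(record.species, record.protein_id,
                         "architecture: " + "; ".join(reasons))
    if evidence.rbh_partner is not None and evidence.rbh_partner_family != family:
        return Rejection(record.species, record.protein_id,
                         "reciprocal best reference hit is outside the family")
    return AnnotationRecord(
        species=record.species, protein_id=record.protein_id, family=family,
        rbh=evidence.rbh_partner_family == family,
        cluster=evidence.orthogroup_family == family,
        profile=family in evidence.profile_families,
        architecture=True,
    )


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

def copy_number_matrix(records: Sequence[AnnotationRecord],
                       species: Sequence[str],
                       families: Sequence[str]) -> pd.DataFrame:
    """Species x family matrix of accepted copies, zero-filled."""
    mat = pd.DataFrame(0, index=sorted(species), columns=sorted(families),
                       dtype=int)
    for r in records:
        if r.species in mat.index and r.family in mat.columns:
            mat.loc[r.species, r.family] += 1
    mat.index.name = "species"
    return mat


def write_copy_number_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t")
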