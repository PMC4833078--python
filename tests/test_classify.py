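"""Functional classification: architecture checks, residue-anchored calls,
TEP/TLR/Relish classes, evidence integration, and copy numbers."""

import numpy as np
import pytest

from immgene import classify
from immgene.align import MultipleAlignment, ResidueAnchor, progressive_msa
from immgene.classify import (EvidenceBundle, Rejection, TEPCall,
                              check_architecture, classify_tlr,
                              copy_number_matrix, glucanase_activity_call,
                              integrate_evidence, pgrp_catalytic_call,
                              relish_architecture, tep_classify)
from immgene.features import CysCluster, StructureProfile, TMSegment
from immgene.io_formats import AnnotationRecord, FamilyRule, ProteinRecord
from immgene.motifscan import DomainHit, MotifHit
from immgene.synthetic_data import build_protein

from conftest import random_protein


def _struct(loc="transmembrane", tm=None, lrrs=None, clusters=None,
            signal=True):
    return StructureProfile("s", "p", signal, tm or [], lrrs or [],
                            clusters or [], loc)


def _dh(name, start=1, end=100):
    return DomainHit("s", "p", name, start, end, 100.0)


TLR_RULE = FamilyRule("TLR", required_domains=(("LRR", 1), ("TIR", 1), ("TM", 1)),
                      localization_expected="transmembrane")


def test_full_tlr_architecture_passes():
    rec = ProteinRecord("s", "p", "A" * 100)
    struct = _struct(tm=[TMSegment(200, 224, 3.0)], lrrs=[(30, 40)])
    ok, reasons = check_architecture(rec, TLR_RULE, [_dh("TIR")], [], struct)
    assert ok and reasons == []


def test_missing_tir_fails_with_named_reason():
    rec = ProteinRecord("s", "p", "A" * 100)
    struct = _struct(tm=[TMSegment(200, 224, 3.0)], lrrs=[(30, 40)])
    ok, reasons = check_architecture(rec, TLR_RULE, [], [], struct)
    assert not ok and any("TIR absent" in r for r in reasons)


def test_forbidden_domain_and_localization_clauses():
    rule = FamilyRule("F", required_domains=(("D", 1),),
                      forbidden_domains=("BAD",),
                      localization_expected="secreted")
    rec = ProteinRecord("s", "p", "A" * 50)
    ok, reasons = check_architecture(
        rec, rule, [_dh("D"), _dh("BAD")], [], _struct(loc="intracellular"))
    assert not ok
    assert any("forbidden" in r for r in reasons)
    assert any("localization" in r for r in reasons)


def test_unknown_domain_name_in_rule_raises():
    rule = FamilyRule("F", required_domains=(("NOPE", 1),))
    rec = ProteinRecord("s", "p", "A" * 50)
    with pytest.raises(KeyError, match="NOPE"):
        check_architecture(rec, rule, [], [], _struct(),
                           known_domains={"TIR", "PGRP"})


def test_architecture_on_generated_proteins_with_planted_violations():
    """50 constructs, half with the TIR hit withheld: the pass set equals
    the planted truth."""
    rng = np.random.default_rng(61)
    for k in range(50):
        bp = build_protein("TLR", rng)
        rec = ProteinRecord("s", f"p{k}", bp.sequence)
        from immgene.features import structure_profile
        struct = structure_profile(rec)
        withhold = k % 2 == 1
        hits = [] if withhold else [_dh("TIR")]
        ok, _ = check_architecture(rec, TLR_RULE, hits, [], struct)
        assert ok == (not withhold)


# ---------------------------------------------------------------- residues

TRIAD_ANCHOR = ResidueAnchor("PGRP_triad", "ref", (2, 5, 8),
                             (frozenset("C"), frozenset("H"), frozenset("H")))


def _triad_msa(member_seq):
    return MultipleAlignment(["ref", "m"],
                             {"ref": "ACDEHKLHIV", "m": member_seq})


def test_pgrp_reference_itself_is_catalytic():
    call = pgrp_catalytic_call(_triad_msa("ACDEHKLHIV"), "ref", TRIAD_ANCHOR)
    assert call.state == "catalytic" and not call.asterisk


def test_pgrp_his_to_tyr_substitution_is_noncatalytic():
    call = pgrp_catalytic_call(_triad_msa("ACDEYKLHIV"), "m", TRIAD_ANCHOR)
    assert call.state == "non-catalytic" and call.letters == ("C", "Y", "H")


def test_pgrp_gap_at_anchor_is_noncatalytic_with_dash():
    call = pgrp_catalytic_call(_triad_msa("A-DEHKLHIV"), "m", TRIAD_ANCHOR)
    assert call.state == "non-catalytic" and call.letters[0] == "-"


def test_pgrp_planted_ablations_recovered_through_real_msa():
    """Synthetic PGRP domains, 40% triad-ablated: every call equals the
    planted truth after a real progressive alignment."""
    rng = np.random.default_rng(62)
    from immgene.synthetic_data import _CONSENSI, PGRP_TRIAD_REL, mutate
    cons = _CONSENSI["PGRP"]
    protected = frozenset(p - 1 for p in PGRP_TRIAD_REL)
    recs = [ProteinRecord("s", "ref", cons)]
    truth = {"ref": True}
    for i in range(12):
        seq = mutate(cons, 0.04, rng, protected)
        ablate = i % 5 in (0, 1)
        if ablate:
            out = list(seq)
            out[PGRP_TRIAD_REL[0] - 1] = "S"
            seq = "".join(out)
        recs.append(ProteinRecord("s", f"m{i}", seq))
        truth[f"m{i}"] = not ablate
    msa = progressive_msa(recs)
    anchor = ResidueAnchor("PGRP_triad", "ref", PGRP_TRIAD_REL,
                           (frozenset("C"), frozenset("H"), frozenset("H")))
    for rid, expect in truth.items():
        call = pgrp_catalytic_call(msa, rid, anchor)
        assert (call.state == "catalytic") == expect, rid


def test_glucanase_e_pair_calls():
    anchor = ResidueAnchor("glu", "ref", (3, 8), (frozenset("E"),) * 2)
    msa = MultipleAlignment(["ref", "ok", "q"],
                            {"ref": "AAEAAAAEAA", "ok": "AAEAAAAEAA",
                             "q": "AAQAAAAEAA"})
    assert glucanase_activity_call(msa, "ok", anchor).state == "catalytic"
    call = glucanase_activity_call(msa, "q", anchor)
    assert call.state == "non-catalytic" and call.asterisk


# --------------------------------------------------------------- TEP / TLR

def test_tep_with_motif_is_tep_class():
    call = tep_classify(ProteinRecord("s", "p", "AAAGCGEQAAA"))
    assert call.thioester_motif_present and call.critical_cys_present
    assert call.tep_class == "TEP"


def test_tep_with_mutated_motif_is_mcr_like_without_cys():
    call = tep_classify(ProteinRecord("s", "p", "AAAGAGEQAAA"),
                        motif_region_hint=(4, 8))
    assert not call.thioester_motif_present
    assert not call.critical_cys_present
    assert call.tep_class == "MCR-like"


def test_tep_fallback_window_finds_retained_cysteine():
    # motif degenerated but the cysteine survives nearby
    seq = "AAAGAGEQAA" + "C" + "A" * 20
    call = tep_classify(ProteinRecord("s", "p", seq), motif_region_hint=(4, 8))
    assert not call.thioester_motif_present and call.critical_cys_present


def test_tep_planted_ablation_fixture():
    rng = np.random.default_rng(63)
    n_mcr = 0
    for k in range(20):
        bp = build_protein("TEP", rng)
        call = tep_classify(ProteinRecord("s", f"p{k}", bp.sequence))
        assert ("yes" if call.thioester_motif_present else "no") == bp.thioester
        n_mcr += call.tep_class == "MCR-like"
    assert 0 < n_mcr < 20


def _tlr_struct(clusters):
    return _struct(tm=[TMSegment(200, 224, 3.0)], lrrs=[(30, 40)],
                   clusters=clusters)


def test_tlr_single_juxtamembrane_cluster_is_scc():
    call = classify_tlr(_tlr_struct([CysCluster(180, 190, 2, True)]), True)
    assert call.tlr_class == "scc" and call.cluster_count == 1


def test_tlr_two_clusters_is_mcc():
    call = classify_tlr(_tlr_struct([CysCluster(30, 40, 2, False),
                                     CysCluster(180, 190, 2, True)]), True)
    assert call.tlr_class == "mcc"


def test_tlr_three_clusters_is_atypical():
    call = classify_tlr(_tlr_struct([CysCluster(30, 40, 2, False),
                                     CysCluster(100, 110, 2, False),
                                     CysCluster(180, 190, 2, True)]), True)
    assert call.tlr_class == "atypical" and call.cluster_count == 3


def test_tlr_without_tir_is_an_error():
    with pytest.raises(ValueError, match="TIR"):
        classify_tlr(_tlr_struct([]), False)


def test_tlr_short_ectodomain_flagged_truncated():
    struct = _struct(tm=[TMSegment(100, 124, 3.0)],
                     clusters=[CysCluster(80, 90, 2, True)])
    assert classify_tlr(struct, True).truncated


def test_relish_architecture_patterns():
    full = [_dh("RHD", 20, 200), _dh("ANK", 220, 252), _dh("ANK", 260, 292)]
    rec = ProteinRecord("s", "p", "A" * 300)
    assert relish_architecture(rec, full) == (True, True)
    assert relish_architecture(rec, [_dh("RHD", 20, 200)]) == (True, False)
    # ankyrins N-terminal of the RHD do not count as the C-terminal region
    wrong_order = [_dh("RHD", 200, 380), _dh("ANK", 20, 52), _dh("ANK", 60, 92)]
    assert relish_architecture(rec, wrong_order) == (True, False)


# ------------------------------------------------------------ integration

RULES = {"PGRP": FamilyRule("PGRP", required_domains=(("PGRP", 1),)),
         "TEP": FamilyRule("TEP", required_domains=(("TED", 1),))}


def test_cluster_label_plus_architecture_is_accepted():
    rec = ProteinRecord("s", "p", "A" * 50)
    ev = EvidenceBundle(orthogroup_family="PGRP", domain_hits=[_dh("PGRP")])
    out = integrate_evidence(rec, ev, RULES, _struct(loc="secreted"))
    assert isinstance(out, AnnotationRecord)
    assert out.family == "PGRP" and out.cluster and not out.rbh


def test_reciprocal_hit_outside_family_rejects():
    rec = ProteinRecord("s", "p", "A" * 50)
    ev = EvidenceBundle(orthogroup_family="PGRP", domain_hits=[_dh("PGRP")],
                        rbh_partner="other_gene", rbh_partner_family=None)
    out = integrate_evidence(rec, ev, RULES, _struct(loc="secreted"))
    assert isinstance(out, Rejection) and "reciprocal" in out.reason


def test_architecture_failure_rejects_with_reason():
    rec = ProteinRecord("s", "p", "A" * 50)
    ev = EvidenceBundle(orthogroup_family="PGRP")  # no PGRP domain hit
    out = integrate_evidence(rec, ev, RULES, _struct(loc="secreted"))
    assert isinstance(out, Rejection) and "architecture" in out.reason


def test_tied_multi_family_evidence_rejects():
    rec = ProteinRecord("s", "p", "A" * 50)
    ev = EvidenceBundle(orthogroup_family="PGRP", profile_families={"TEP"},
                        domain_hits=[_dh("PGRP"), _dh("TED")])
    out = integrate_evidence(rec, ev, RULES, _struct(loc="secreted"))
    assert isinstance(out, Rejection) and "ambiguous" in out.reason


def test_no_family_evidence_returns_none():
    rec = ProteinRecord("s", "p", "A" * 50)
    assert integrate_evidence(rec, EvidenceBundle(), RULES,
                              _struct(loc="secreted")) is None


# ------------------------------------------------------------ copy numbers

def test_copy_number_matrix_zero_filled_shape():
    mat = copy_number_matrix([], ["a", "b"], ["F1", "F2", "F3"])
    assert mat.shape == (2, 3) and (mat.values == 0).all()


def test_copy_number_matrix_hand_tally():
    recs = ([AnnotationRecord("a", f"p{i}", "F1", cluster=True) for i in range(3)]
            + [AnnotationRecord("a", f"q{i}", "F2", cluster=True) for i in range(2)]
            + [AnnotationRecord("b", f"r{i}", "F1", cluster=True) for i in range(4)])
    mat = copy_number_matrix(recs, ["a", "b", "c"], ["F1", "F2"])
    assert mat.loc["a", "F1"] == 3 and mat.loc["a", "F2"] == 2
    assert mat.loc["b", "F1"] == 4 and mat.loc["b", "F2"] == 0
    assert (mat.loc["c"] == 0).all()
    assert int(mat.values.sum()) == len(recs)
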