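"""End-to-end orchestration of the annotation procedure.

Stage order mirrors the combined-evidence protocol: read inputs, collapse
suspected haplotype duplicates, all-vs-all local-alignment search, filter at
the published thresholds, reciprocal best hits against the reference species
plus orthogroup clustering, motif and PSSM scans, structural features,
functional classification, evidence integration, the copy-number matrix,
and per-family domain alignments with midpoint-rooted bootstrapped NJ
trees.  Every stage's outputs are written; the run log records one
structured line per stage with record counts.  The whole run is
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, features, homology, motifscan, phylo
from .align import MultipleAlignment, ResidueAnchor, progressive_msa
from .io_formats import (AnnotationRecord, ProteinRecord, RuleSet,
                         read_fasta, read_query_set, read_ruleset,
                         write_annotation_table)
from .motifscan import PSSM, build_pssm, compile_degenerate_motif


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one annotation run."""

    proteome_paths: dict[str, str]      # species label -> FASTA path
    reference_species: str
    query_set_path: str
    rules_path: str
    domain_alignment_paths: dict[str, str]  # domain name -> aligned FASTA
    output_dir: str
    haplotype_identity: float = 0.99
    pssm_margin: float | None = None  # None: score-proportional default
    bootstrap_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_species not in self.proteome_paths:
            raise ValueError("reference species must be among the input proteomes")
        if not 0 < self.haplotype_identity <= 1:
            raise ValueError("haplotype identity threshold must be in (0, 1]")


@dataclass
class RunResult:
    accepted: list[AnnotationRecord]
    rejections: list[classify.Rejection]
    copy_numbers: pd.DataFrame
    structures: dict[tuple[str, str], features.StructureProfile]
    family_msas: dict[str, MultipleAlignment]
    trees: dict[str, object]
    log: list[str]
    truth_comparison: dict | None = None


def _read_alignment_fasta(path: str, name: str) -> MultipleAlignment:
    ids, rows = [], {}
    with open(path) as fh:
        rid = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                rid = line[1:].split()[0]
                ids.append(rid)
                rows[rid] = ""
            elif rid is not None:
                rows[rid] += line.strip().upper()
    if not ids:
        raise StageFailure(f"domain alignment {name}: empty file {path}")
    return MultipleAlignment(ids, rows)


def run_annotate(config: PipelineConfig, dataset=None) -> RunResult:
    """Run the full annotation procedure and write the output bundle.

    ``dataset`` may be an in-memory :class:`immgene.synthetic_data.Dataset`;
    it then supplies the inputs directly and the path fields of the
    configuration are ignored.
    """
    log: list[str] = []
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, text: str) -> None:
        log.append(f"[{name}] {text}")

    # ------------------------------------------------------------------ read
    try:
        if dataset is not None:
            proteomes = {sp: list(recs) for sp, recs in dataset.proteomes.items()}
            query_families = dict(dataset.query_families)
            ruleset: RuleSet = dataset.ruleset
            domain_msas = {
                name: MultipleAlignment([rid for rid, _ in rows],
                                        {rid: row for rid, row in rows})
                for name, rows in dataset.domain_alignments.items()
            }
        else:
            proteomes = {sp: read_fasta(path, species=sp)
                         for sp, path in sorted(config.proteome_paths.items())}
            qrecs, query_families = read_query_set(
                config.query_set_path, config.reference_species)
            ruleset = read_ruleset(config.rules_path)
            domain_msas = {name: _read_alignment_fasta(path, name)
                           for name, path in
                           sorted(config.domain_alignment_paths.items())}
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageFailure(f"read: {exc}") from exc
    ref = config.reference_species
    species = sorted(proteomes)
    stage("read", f"{len(species)} proteomes, "
                  f"{sum(len(v) for v in proteomes.values())} proteins, "
                  f"{len(query_families)} query proteins")

    # ------------------------------------------------- collapse haplotypes
    collapsed: dict[str, list[ProteinRecord]] = {}
    n_merged = 0
    for sp in species:
        kept, report = homology.collapse_haplotypes(
            proteomes[sp], identity_threshold=config.haplotype_identity)
        collapsed[sp] = kept
        n_merged += len(report.merges)
    stage("collapse_haplotypes", f"{n_merged} merged")
    all_records = [r for sp in species for r in collapsed[sp]]
    by_key = {r.key: r for r in all_records}

    # ------------------------------------------------------- all-vs-all
    hits = homology.all_vs_all_search(all_records)
    stage("search", f"{len(hits)} raw hit rows")
    filtered = homology.filter_hits_blast(hits)
    stage("filter", f"{len(filtered)} rows pass thresholds")

    # ------------------------------------------------- RBH + orthogroups
    rbh = homology.best_reciprocal_hits(filtered, ref)
    rbh_by_protein = {key: rid for rid, key in rbh}
    groups = homology.cluster_orthogroups(
        filtered, [r.key for r in all_records],
        query_families=query_families, reference_species=ref)
    group_family: dict[tuple[str, str], str | None] = {}
    for og in groups:
        for key in og.members:
            group_family[key] = og.family if not og.ambiguous else None
    stage("orthogroups", f"{len(rbh)} RBH pairs, {len(groups)} groups")

    # ------------------------------------------------- motif / PSSM scans
    try:
        pssms: dict[str, PSSM] = {
            name: build_pssm(msa, margin=config.pssm_margin, name=name)
            for name, msa in sorted(domain_msas.items())
        }
    except Exception as exc:
        raise StageFailure(f"build_pssm: {exc}") from exc
    motifs = {mid: compile_degenerate_motif(pat, mid)
              for mid, pat in sorted(ruleset.motifs.items())}
    domain_hits: dict[tuple[str, str], list[motifscan.DomainHit]] = {}
    motif_hits: dict[tuple[str, str], list[motifscan.MotifHit]] = {}
    for rec in all_records:
        dh = []
        for name, pssm in pssms.items():
            dh.extend(motifscan.scan_pssm(rec, pssm))
        domain_hits[rec.key] = dh
        mh = []
        for mid, motif in motifs.items():
            mh.extend(motifscan.scan_motif(rec, motif))
        motif_hits[rec.key] = mh
    stage("scan", f"{sum(len(v) for v in domain_hits.values())} domain hits, "
                  f"{sum(len(v) for v in motif_hits.values())} motif hits")

    # ------------------------------------------------------------ features
    structures = {rec.key: features.structure_profile(rec)
                  for rec in all_records}
    stage("features", f"{len(structures)} structure profiles")

    # ----------------------------------- evidence integration per protein
    # map each non-structural required domain / required motif to its family
    domain_family: dict[str, str] = {}
    motif_only_families: dict[str, str] = {}
    for fam, rule in ruleset.families.items():
        real_domains = [d for d, _ in rule.required_domains
                        if d not in classify.STRUCTURAL_DOMAINS]
        for d in real_domains:
            domain_family[d] = fam
        if not real_domains:
            for m in rule.required_motifs:
                motif_only_families[m] = fam
    known_domains = set(pssms)

    accepted: list[AnnotationRecord] = []
    rejections: list[classify.Rejection] = []
    for rec in all_records:
        profile_fams = {domain_family[h.name] for h in domain_hits[rec.key]
                        if h.name in domain_family}
        # a motif-model family's degenerate-pattern hit is profile evidence
        profile_fams |= {motif_only_families[m.name]
                         for m in motif_hits[rec.key]
                         if m.name in motif_only_families}
        partner = rbh_by_protein.get(rec.key)
        evidence = classify.EvidenceBundle(
            rbh_partner=partner,
            rbh_partner_family=query_families.get(partner) if partner else None,
            orthogroup_family=group_family.get(rec.key),
            profile_families=profile_fams,
            domain_hits=domain_hits[rec.key],
            motif_hits=motif_hits[rec.key],
        )
        result = classify.integrate_evidence(rec, evidence, ruleset.families,
                                             structures[rec.key],
                                             known_domains=known_domains)
        if isinstance(result, AnnotationRecord):
            accepted.append(result)
        elif isinstance(result, classify.Rejection):
            rejections.append(result)
    stage("integrate", f"{len(accepted)} accepted, {len(rejections)} rejected")

    # --------------------------------------- per-family functional calls
    family_members: dict[str, list[AnnotationRecord]] = {}
    for ann in accepted:
        family_members.setdefault(ann.family, []).append(ann)
    family_msas: dict[str, MultipleAlignment] = {}
    trees: dict[str, object] = {}

    for fam in sorted(family_members):
        members = sorted(family_members[fam],
                         key=lambda a: (a.species, a.protein_id))
        rule = ruleset.families[fam]
        _annotate_family(fam, rule, members, by_key, ruleset, domain_msas,
                         domain_hits, motif_hits, structures,
                         family_msas, config, trees)
    stage("classify", f"functional calls for {len(family_members)} families")

    # ------------------------------------------------------- copy numbers
    copy_numbers = classify.copy_number_matrix(
        accepted, species, sorted(ruleset.families))
    stage("copy_numbers", f"{int(copy_numbers.values.sum())} accepted copies")

    # ------------------------------------------------------------- output
    write_annotation_table(accepted, out / "annotation.tsv")
    classify.write_copy_number_matrix(copy_numbers, out / "copy_numbers.tsv")
    features.write_feature_table(
        [structures[k] for k in sorted(structures)], out / "features.tsv")
    homology.write_hit_table(filtered, out / "filtered_hits.tsv")
    (out / "trees").mkdir(exist_ok=True)
    for fam in sorted(trees):
        phylo.write_newick(trees[fam], out / "trees" / f"{fam}.nwk")
    (out / "alignments").mkdir(exist_ok=True)
    for fam in sorted(family_msas):
        family_msas[fam].write_fasta(out / "alignments" / f"{fam}.afa")
    with open(out / "rejections.tsv", "w") as fh:
        fh.write("species\tprotein_id\treason\n")
        for r in sorted(rejections, key=lambda r: (r.species, r.protein_id)):
            fh.write(f"{r.species}\t{r.protein_id}\t{r.reason}\n")
    run_info = {
        "seed": config.seed,
        "reference_species": ref,
        "haplotype_identity": config.haplotype_identity,
        "pssm_margin": config.pssm_margin,
        "bootstrap_replicates": config.bootstrap_replicates,
        "thresholds": {"blast_evalue": homology.BLAST_EVALUE,
                       "blast_identity": homology.BLAST_IDENTITY,
                       "blast_bitscore": homology.BLAST_BITSCORE},
    }
    with open(out / "run_info.json", "w") as fh:
        json.dump(run_info, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return RunResult(accepted=accepted, rejections=rejections,
                     copy_numbers=copy_numbers, structures=structures,
                     family_msas=family_msas, trees=trees, log=log)


def _annotate_family(fam: str, rule, members, by_key, ruleset, domain_msas,
                     domain_hits, motif_hits, structures, family_msas,
                     config: PipelineConfig, trees) -> None:
    """Family-level functional annotation: residue calls on domain-region
    alignments, thioester/TLR/Relish calls, localization; builds the family
    domain MSA and its bootstrapped midpoint-rooted NJ tree."""
    # extract each member's diagnostic-domain region (falls back to the
    # full sequence when the family has no single domain model)
    domain_names = [d for d, _ in rule.required_domains
                    if d not in classify.STRUCTURAL_DOMAINS]
    dom = domain_names[0] if domain_names else None

    # MSA member ids are species-qualified: gene-tree leaves must be unique
    # across species while protein ids are only unique within one
    region_records: list[ProteinRecord] = []
    offsets: dict[str, int] = {}  # qualified id -> 0-based region start
    for ann in members:
        rec = by_key[(ann.species, ann.protein_id)]
        qid = f"{ann.species}|{ann.protein_id}"
        if dom is not None:
            hits = [h for h in domain_hits[rec.key] if h.name == dom]
            if not hits:
                raise StageFailure(
                    f"classify: {fam}: {rec.species}/{rec.protein_id} accepted "
                    f"without a {dom} hit")
            h = max(hits, key=lambda h: h.score)
            region = rec.sequence[h.start - 1:h.end]
            offsets[qid] = h.start - 1
        else:
            region = rec.sequence
            offsets[qid] = 0
        region_records.append(ProteinRecord(rec.species, qid, region))

    msa = progressive_msa(region_records)
    family_msas[fam] = msa

    # residue-anchored calls need the anchor's reference qualified and its
    # positions shifted into region coordinates
    anchors: dict[str, ResidueAnchor] = {}
    for aid in rule.residue_anchors:
        anchor = ruleset.anchors[aid]
        qref = f"{config.reference_species}|{anchor.reference_id}"
        if qref in msa.rows:
            anchors[aid] = ResidueAnchor(
                anchor.anchor_id, qref,
                tuple(p - offsets[qref] for p in anchor.positions),
                anchor.expected)

    for ann in members:
        rec = by_key[(ann.species, ann.protein_id)]
        qid = f"{ann.species}|{ann.protein_id}"
        struct = structures[rec.key]
        func = ann.functional
        func["localization"] = struct.localization
        if fam == "PGRP":
            if "PGRP_triad" in anchors:
                call = classify.pgrp_catalytic_call(
                    msa, qid, anchors["PGRP_triad"], ann.species)
                func["catalytic"] = "yes" if call.state == "catalytic" else "no"
            has_rhim, _ = motifscan.scan_rhim(rec)
            func["rhim"] = "yes" if has_rhim else "no"
        elif fam == "BGRP":
            if "GH16_glu_pair" in anchors:
                call = classify.glucanase_activity_call(
                    msa, qid, anchors["GH16_glu_pair"], ann.species)
                func["catalytic"] = "yes" if call.state == "catalytic" else "no"
        elif fam == "TEP":
            # expected motif region: where GCGEQ sits in the domain model,
            # mapped through the member's domain hit
            hint = None
            ted_hits = [h for h in domain_hits[rec.key] if h.name == "TED"]
            if ted_hits and "TED" in domain_msas:
                model = domain_msas["TED"]
                ref_row = model.degapped(model.ids[0])
                rel = ref_row.find(classify.THIOESTER_MOTIF)
                if rel >= 0:
                    h = max(ted_hits, key=lambda h: h.score)
                    start = h.start + rel
                    hint = (start, start + 4)
            call = classify.tep_classify(rec, motif_region_hint=hint)
            func["thioester"] = "yes" if call.thioester_motif_present else "no"
            func["tep_class"] = call.tep_class
        elif fam == "TLR":
            tir = any(h.name == "TIR" for h in domain_hits[rec.key])
            call = classify.classify_tlr(struct, tir_present=tir)
            func["tlr_class"] = call.tlr_class
            func["truncated"] = "yes" if call.truncated else "no"
        elif fam == "Relish":
            has_rhd, has_ank = classify.relish_architecture(
                rec, domain_hits[rec.key])
            func["ankyrin"] = "yes" if has_ank else "no"

    if len(msa.ids) >= 3:
        trees[fam] = phylo.bootstrap_support(
            msa, n_replicates=config.bootstrap_replicates, seed=config.seed)


# ---------------------------------------------------------------------------
# Verification against a truth table
# ---------------------------------------------------------------------------

FUNCTIONAL_TRUTH_FIELDS = {
    "catalytic": "catalytic",
    "thioester": "thioester",
    "tlr_class": "tlr_class",
    "localization": "localization",
    "ankyrin": "ankyrin",
}


def verify(accepted: list[AnnotationRecord], truth: pd.DataFrame,
           copy_numbers: pd.DataFrame | None = None) -> dict:
    """Precision/recall of family assignment and agreement of functional
    calls against a generator truth table."""
    truth_fam = {(r.species, r.protein_id): r.family
                 for r in truth.itertuples() if r.family != "background"}
    called = {(a.species, a.protein_id): a.family for a in accepted}
    tp = sum(1 for k, fam in called.items() if truth_fam.get(k) == fam)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(truth_fam) if truth_fam else 1.0

    per_family: dict[str, dict] = {}
    fams = sorted({f for f in truth_fam.values()} | set(called.values()))
    for fam in fams:
        t = {k for k, f in truth_fam.items() if f == fam}
        c = {k for k, f in called.items() if f == fam}
        per_family[fam] = {
            "precision": len(t & c) / len(c) if c else 1.0,
            "recall": len(t & c) / len(t) if t else 1.0,
        }

    truth_rows = {(r.species, r.protein_id): r for r in truth.itertuples()}
    func_agreement: dict[str, dict] = {}
    for field_name, truth_col in FUNCTIONAL_TRUTH_FIELDS.items():
        n = agree = 0
        for a in accepted:
            row = truth_rows.get((a.species, a.protein_id))
            if row is None:
                continue
            truth_val = getattr(row, truth_col)
            call_val = a.functional.get(field_name)
            if truth_val == "." or call_val is None:
                continue
            n += 1
            agree += int(call_val == truth_val)
        func_agreement[field_name] = {
            "n": n, "agreement": agree / n if n else 1.0}

    out = {"family_precision": precision, "family_recall": recall,
           "n_called": len(called), "n_truth": len(truth_fam),
           "per_family": per_family, "functional": func_agreement}

    if copy_numbers is not None:
        planted = (truth[truth.family != "background"]
                   .groupby(["species", "family"]).size())
        expected = copy_numbers.copy()
        expected.loc[:, :] = 0
        for (sp, fam), n in planted.items():
            if sp in expected.index and fam in expected.columns:
                expected.loc[sp, fam] = n
        out["copy_number_exact"] = bool((expected == copy_numbers).all().all())
    return out
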