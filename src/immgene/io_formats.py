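"""Readers and writers for the formats the annotation pipeline consumes.

Protein FASTA in and out, tab-separated annotation tables, the family-rule
configuration (a documented YAML schema, see :func:`read_ruleset`), and small
helpers shared by every downstream module.  All coordinates in files and in
public report objects are 1-based inclusive, matching the residue-numbering
convention of the field (e.g. "E188"); purely internal computations use
0-based half-open ranges and convert at this layer.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: the 20 canonical residues plus the ambiguity letter X
ALPHABET = AA20 + "X"
_ALPHABET_SET = frozenset(ALPHABET)

LOCALIZATIONS = ("secreted", "transmembrane", "intracellular")


class FormatError(ValueError):
    """Malformed input file; the message names the offending record."""


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted peptide from one species."""

    species: str
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.species}/{self.protein_id}: empty sequence")
        if any(ch.isspace() for ch in self.protein_id) or not self.protein_id:
            raise FormatError(f"invalid protein id {self.protein_id!r}")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise FormatError(
                f"{self.species}/{self.protein_id}: illegal residue letters "
                f"{sorted(bad)} (alphabet is the 20 amino acids plus X)"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.protein_id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FamilyRule:
    """Per-family requirements used by the architecture filter.

    ``required_domains`` maps a domain name to a minimum hit count.  The
    reserved names ``TM`` and ``LRR`` are satisfied from predicted structural
    features rather than domain-model hits.
    """

    family: str
    required_domains: tuple[tuple[str, int], ...] = ()
    forbidden_domains: tuple[str, ...] = ()
    required_motifs: tuple[str, ...] = ()
    residue_anchors: tuple[str, ...] = ()
    localization_expected: str = "any"

    def __post_init__(self) -> None:
        req = {d for d, _ in self.required_domains}
        if req & set(self.forbidden_domains):
            raise FormatError(
                f"rule {self.family}: required and forbidden domains overlap: "
                f"{sorted(req & set(self.forbidden_domains))}"
            )
        if not self.required_domains and not self.required_motifs:
            raise FormatError(
                f"rule {self.family}: needs at least one required domain or motif"
            )
        if self.localization_expected not in LOCALIZATIONS + ("any",):
            raise FormatError(
                f"rule {self.family}: unknown localization "
                f"{self.localization_expected!r}"
            )


@dataclass
class AnnotationRecord:
    """A protein's family call plus the evidence that supports it."""

    species: str
    protein_id: str
    family: str
    rbh: bool = False
    cluster: bool = False
    profile: bool = False
    architecture: bool = False
    functional: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.rbh or self.cluster or self.profile or self.architecture):
            raise FormatError(
                f"{self.species}/{self.protein_id}: accepted record must carry "
                "at least one evidence flag"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, species: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    ``species`` defaults to the file stem.  Sequences are uppercased, terminal
    stop characters (``*``) stripped; internal stops or letters outside the
    21-letter alphabet raise :class:`FormatError` naming the record.  The
    empty file yields an empty list.
    """
    path = Path(path)
    sp = species if species is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if not pid:
            raise FormatError(f"{path}: record with empty header")
        if pid in seen:
            raise FormatError(f"{path}: duplicate record id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper().strip("*")
        if "*" in seq:
            raise FormatError(f"{path}:{pid}: internal stop codon ('*')")
        if not seq:
            raise FormatError(f"{path}:{pid}: empty sequence")
        bad = set(seq) - _ALPHABET_SET
        if bad:
            raise FormatError(f"{path}:{pid}: illegal letters {sorted(bad)}")
        records.append(ProteinRecord(sp, pid, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike,
                descriptions: Mapping[tuple[str, str], str] | None = None) -> None:
    """Write records in the given order; optional per-record description text."""
    seqs = []
    for r in records:
        desc = descriptions.get(r.key, "") if descriptions else ""
        seqs.append(SeqRecord(Seq(r.sequence), id=r.protein_id, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_query_set(path: str | os.PathLike, species: str) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Read the labeled reference query set.

    Headers carry the family as a ``family=NAME`` token in the description,
    e.g. ``>PGRP_og0_c1 family=PGRP``.  Returns the records plus a mapping
    protein_id -> family.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    families: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fam = None
        for token in rec.description.split():
            if token.startswith("family="):
                fam = token.split("=", 1)[1]
        if fam is None:
            raise FormatError(f"{path}:{rec.id}: query record lacks family= tag")
        seq = str(rec.seq).upper().strip("*")
        records.append(ProteinRecord(species, rec.id, seq))
        families[rec.id] = fam
    return records, families


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_HEADER = (
    "species\tprotein_id\tfamily\tevidence_rbh\tevidence_cluster\t"
    "evidence_profile\tevidence_architecture\tfunctional"
)


def _functional_str(d: Mapping[str, str]) -> str:
    return ";".join(f"{k}={d[k]}" for k in sorted(d)) if d else "."


def _parse_functional(text: str) -> dict[str, str]:
    if text == ".":
        return {}
    out: dict[str, str] = {}
    for item in text.split(";"):
        k, _, v = item.partition("=")
        out[k] = v
    return out


def write_annotation_table(records: Sequence[AnnotationRecord], path: str | os.PathLike) -> None:
    """Write a TSV annotation table; rows sorted (species, family, protein_id)."""
    rows = sorted(records, key=lambda r: (r.species, r.family, r.protein_id))
    with open(path, "w") as fh:
        fh.write(ANNOTATION_HEADER + "\n")
        for r in rows:
            fh.write(
                f"{r.species}\t{r.protein_id}\t{r.family}\t"
                f"{int(r.rbh)}\t{int(r.cluster)}\t{int(r.profile)}\t"
                f"{int(r.architecture)}\t{_functional_str(r.functional)}\n"
            )


def read_annotation_table(path: str | os.PathLike) -> list[AnnotationRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != ANNOTATION_HEADER:
            raise FormatError(f"{path}: unexpected annotation-table header")
        out = []
        for line in fh:
            sp, pid, fam, rbh, clu, prof, arch, func = line.rstrip("\n").split("\t")
            out.append(AnnotationRecord(
                sp, pid, fam,
                rbh=bool(int(rbh)), cluster=bool(int(clu)),
                profile=bool(int(prof)), architecture=bool(int(arch)),
                functional=_parse_functional(func),
            ))
    return out


# ---------------------------------------------------------------------------
# Family-rule configuration
# ---------------------------------------------------------------------------

class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys (duplicate rules)."""


def _construct_mapping_no_dup(loader: _StrictLoader, node: yaml.MappingNode):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=True)
        if key in mapping:
            raise FormatError(f"duplicate key {key!r} in configuration")
        mapping[key] = loader.construct_object(value_node, deep=True)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping_no_dup
)


@dataclass
class RuleSet:
    """Parsed family-rule configuration.

    ``motifs`` maps motif id -> degenerate pattern string; ``anchors`` maps
    anchor id -> :class:`immgene.align.ResidueAnchor`.
    """

    families: dict[str, FamilyRule]
    motifs: dict[str, str] = field(default_factory=dict)
    anchors: dict[str, object] = field(default_factory=dict)


def _rule_from_mapping(name: str, raw: Mapping) -> FamilyRule:
    req = raw.get("required_domains") or {}
    if isinstance(req, Mapping):
        required = tuple(sorted((str(k), int(v)) for k, v in req.items()))
    else:  # list of names, min count 1
        required = tuple(sorted((str(k), 1) for k in req))
    return FamilyRule(
        family=name,
        required_domains=required,
        forbidden_domains=tuple(sorted(raw.get("forbidden_domains") or ())),
        required_motifs=tuple(raw.get("required_motifs") or ()),
        residue_anchors=tuple(raw.get("residue_anchors") or ()),
        localization_expected=raw.get("localization", "any"),
    )


def read_ruleset(path: str | os.PathLike) -> RuleSet:
    """Parse the full rule configuration.

    Schema (YAML)::

        families:
          PGRP:
            required_domains: {PGRP: 1}   # name -> min count; TM/LRR reserved
            forbidden_domains: []
            required_motifs: []
            residue_anchors: [PGRP_triad]
            localization: any             # secreted|transmembrane|intracellular|any
        motifs:
          NIM: CXPXCXXXCXNGXCXXPXXCXCXXGY
        anchors:
          PGRP_triad:
            reference: PGRP_og0_c1        # protein id of the annotated exemplar
            positions: [66, 109, 117]     # 1-based positions in that sequence
            expected: [C, H, H]           # allowed letters per position
    """
    from .align import ResidueAnchor  # local import: align depends on this module

    with open(path) as fh:
        raw = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(raw, Mapping) or "families" not in raw:
        raise FormatError(f"{path}: expected a top-level 'families' mapping")
    families = {
        name: _rule_from_mapping(name, spec or {})
        for name, spec in raw["families"].items()
    }
    motifs = {str(k): str(v) for k, v in (raw.get("motifs") or {}).items()}
    anchors = {}
    for aid, spec in (raw.get("anchors") or {}).items():
        anchors[aid] = ResidueAnchor(
            anchor_id=aid,
            reference_id=str(spec["reference"]),
            positions=tuple(int(p) for p in spec["positions"]),
            expected=tuple(frozenset(str(e)) for e in spec["expected"]),
        )
    return RuleSet(families=families, motifs=motifs, anchors=anchors)


def read_family_rules(path: str | os.PathLike) -> dict[str, FamilyRule]:
    """Mapping family name -> validated :class:`FamilyRule`."""
    return read_ruleset(path).families


def write_ruleset(ruleset: RuleSet, path: str | os.PathLike) -> None:
    """Serialize a RuleSet back to the YAML schema of :func:`read_ruleset`."""
    doc: dict = {"families": {}, "motifs": dict(sorted(ruleset.motifs.items())),
                 "anchors": {}}
    for name in sorted(ruleset.families):
        r = ruleset.families[name]
        doc["families"][name] = {
            "required_domains": {d: n for d, n in r.required_domains},
            "forbidden_domains": list(r.forbidden_domains),
            "required_motifs": list(r.required_motifs),
            "residue_anchors": list(r.residue_anchors),
            "localization": r.localization_expected,
        }
    for aid in sorted(ruleset.anchors):
        a = ruleset.anchors[aid]
        doc["anchors"][aid] = {
            "reference": a.reference_id,
            "positions": list(a.positions),
            "expected": ["".join(sorted(e)) for e in a.expected],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
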