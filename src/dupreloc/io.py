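"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython, Newick through dendropy; similarity-hit
tables use the 12-column BLAST tabular (outfmt 6) dialect; localization
tables are TSVs with a controlled compartment vocabulary.  All readers
raise typed errors carrying file/line context rather than skipping rows
silently (the one exception: an empty FASTA file is a logged warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input; message carries file and line context."""


#: Compartment vocabulary (Table-style abbreviations).  Comparison is
#: case-insensitive but "cyb" (cytosolic body) is distinct from "cy".
COMPARTMENT_VOCABULARY = frozenset({
    "cp", "cpl", "cy", "cyb", "ck", "cw", "en", "er", "lb", "mt", "nu",
    "per", "pm", "tgn/pvc", "va",
})

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")
NT_ALPHABET = set("ACGTUNRYSWKMBDHV-")


@dataclass
class HitRecord:
    """One row of a BLAST outfmt-6 style tabular hit file."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    extra: tuple = field(default_factory=tuple)


@dataclass
class LocalizationRecord:
    """Per-gene subcellular localization evidence (GFP studies)."""

    gene: str
    compartments: frozenset[str]
    study: str
    condition: str
    evidence: str = "GFP"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: set | None = None) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping (order preserved).

    Raises on duplicate ids or characters outside ``alphabet`` (when
    given); an empty file yields an empty mapping with a warning.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq)
        if alphabet is not None:
            bad = set(seq.upper()) - alphabet
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}")
        out[rec.id] = seq
    if not out:
        logger.warning("%s: empty FASTA file", path)
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree; internal labels are bootstrap supports."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree_list(path) -> list[dendropy.Tree]:
    """Read a file of Newick trees (e.g. a bootstrap set) on a shared taxon
    namespace."""
    path = Path(path)
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=True)
    if len(trees) == 0:
        raise FormatError(f"{path}: no trees found")
    return list(trees)


# ---------------------------------------------------------------------------
# BLAST tabular


def read_hit_table(path, strict: bool = True) -> list[HitRecord]:
    """Parse a 12+-column tab-separated similarity hit table."""
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                msg = f"{path}:{lineno}: expected >=12 columns, got {len(fields)}"
                if strict:
                    raise FormatError(msg)
                logger.warning(msg)
                continue
            try:
                hits.append(HitRecord(
                    query=fields[0], subject=fields[1],
                    pct_identity=float(fields[2]), aln_length=int(fields[3]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                    extra=tuple(fields[4:10]) + tuple(fields[12:]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if hits[-1].evalue < 0 or hits[-1].aln_length < 1:
                raise FormatError(
                    f"{path}:{lineno}: e-value must be >= 0 and alignment length >= 1")
    return hits


# ---------------------------------------------------------------------------
# localization tables


def parse_compartments(token_field: str, on_unknown: str = "error") -> frozenset[str]:
    """Split a semicolon-separated compartment list into a canonical set."""
    tokens = [t.strip() for t in token_field.split(";") if t.strip()]
    if not tokens:
        raise FormatError("empty compartment token set")
    canonical = []
    for tok in tokens:
        low = tok.lower()
        if low not in COMPARTMENT_VOCABULARY:
            msg = f"unknown compartment token {tok!r}"
            if on_unknown == "error":
                raise FormatError(msg)
            logger.warning(msg)
        canonical.append(low)
    return frozenset(canonical)


def read_localization_table(path, on_unknown: str = "error") -> list[LocalizationRecord]:
    """Read a localization TSV: gene, compartments, study, condition[, evidence].

    The compartments field is a semicolon-separated token list from the
    controlled vocabulary.
    """
    path = Path(path)
    records: list[LocalizationRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene", "compartments", "study", "condition"]
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(required):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
            try:
                comps = parse_compartments(fields[idx["compartments"]], on_unknown)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(LocalizationRecord(
                gene=fields[idx["gene"]],
                compartments=comps,
                study=fields[idx["study"]],
                condition=fields[idx["condition"]],
                evidence=fields[idx["evidence"]] if "evidence" in idx else "GFP",
            ))
    return records


def pair_records_comparable(rec1: LocalizationRecord, rec2: LocalizationRecord,
                            strict_same_study: bool = True) -> bool:
    """Localization comparisons across studies/conditions are unreliable
    (localization can vary by condition, organ and age); under the strict
    rule a pair is only usable when both records come from the same study
    under the same condition."""
    if not strict_same_study:
        return True
    return rec1.study == rec2.study and rec1.condition == rec2.condition
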