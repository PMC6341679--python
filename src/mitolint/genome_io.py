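"""Reading and writing annotated mitochondrial genome records.

Input is the GenBank flat-file format (single- or multi-record), parsed with
Biopython, or a plain TSV annotation table plus FASTA genome for fixtures.
All coordinates are 1-based inclusive (GenBank convention); genomes are
treated as circular, so a feature may wrap the origin (start > end).

Feature labels are pushed through :func:`mitolint.gene_names.normalize_gene_name`
at parse time; labels that cannot be mapped are collected as parse warnings on
the record rather than silently kept or dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .gene_names import (
    AMBIGUOUS,
    AMBIGUOUS_LEU,
    AMBIGUOUS_SER,
    CONTROL_REGION,
    LIGHT_STRAND_ORIGIN,
    PROTEIN_GENES,
    PROTEIN_LABELS,
    RRNA_GENES,
    TRNA_GENES,
    TRNA_PRODUCTS,
    UnmappableLabel,
    normalize_gene_name,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature: canonical name, 1-based inclusive span, strand.

    ``start > end`` encodes a feature wrapping the circular origin.
    ``strand`` is +1 (plus/heavy annotation orientation) or -1 (minus).
    ``source_label`` preserves the raw label found in the input.
    """

    name: str
    start: int
    end: int
    strand: int
    source_label: str = ""

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def unrolled_end(self, genome_length: int) -> int:
        """End coordinate on the unrolled circle (may exceed genome length)."""
        return self.end if self.end >= self.start else self.end + genome_length


@dataclass
class MitogenomeRecord:
    """One annotated circular mitochondrial genome."""

    accession: str
    organism: str
    taxon_order: str
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    declared_complete: bool = True
    parse_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: record has no sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def get(self, name: str) -> GeneAnnotation | None:
        """The unique annotation named ``name``, or None."""
        hits = [a for a in self.annotations if a.name == name]
        return hits[0] if len(hits) == 1 else (hits[0] if hits else None)

    def get_all(self, name: str) -> list[GeneAnnotation]:
        return [a for a in self.annotations if a.name == name]

    def sorted_annotations(self) -> list[GeneAnnotation]:
        return sorted(self.annotations, key=lambda a: (a.start, a.end, a.name))

    def copy(self) -> "MitogenomeRecord":
        return dataclasses.replace(
            self,
            annotations=list(self.annotations),
            parse_warnings=list(self.parse_warnings),
        )


class GenBankParseError(ValueError):
    pass


def extract_gene_sequence(record: MitogenomeRecord, ann: GeneAnnotation) -> str:
    """Gene sequence in annotated reading orientation.

    Plus strand: the substring ``start..end``; minus strand: its reverse
    complement.  Wrap-around features concatenate suffix+prefix first.
    """
    L = record.length
    if not (1 <= ann.start <= L and 1 <= ann.end <= L):
        raise ValueError(
            f"{record.accession}:{ann.name} coordinates {ann.start}..{ann.end} "
            f"outside genome of length {L}"
        )
    if ann.start <= ann.end:
        sub = record.sequence[ann.start - 1 : ann.end]
    else:
        sub = record.sequence[ann.start - 1 :] + record.sequence[: ann.end]
    return revcomp(sub) if ann.strand < 0 else sub


# ---------------------------------------------------------------------------
# Ambiguous leucine/serine paralog resolution by syntenic position.
#
# In the conserved mammalian arrangement the copy between rrnL and nad1 is
# trnL2 (UUR); the copy after cox1 is trnS2 (UCN); the copy after trnH is
# trnS1 (AGY); and the copy after trnS1 is trnL1 (CUN).
# ---------------------------------------------------------------------------

_PREV_RULES = {
    AMBIGUOUS_LEU: {"rrnL": "trnL2", "trnS1": "trnL1", AMBIGUOUS_SER: "trnL1"},
    AMBIGUOUS_SER: {"trnH": "trnS1", "cox1": "trnS2"},
}
_NEXT_RULES = {
    AMBIGUOUS_LEU: {"nad1": "trnL2", "nad5": "trnL1"},
    AMBIGUOUS_SER: {"trnL1": "trnS1", AMBIGUOUS_LEU: "trnS1", "trnD": "trnS2"},
}


def resolve_ambiguous_paralogs(
    annotations: list[GeneAnnotation],
) -> tuple[list[GeneAnnotation], list[str]]:
    """Resolve trnL/trnS ambiguity markers using flanking annotations.

    Returns the resolved list (order preserved) and warnings for any marker
    that could not be resolved (those annotations are dropped).
    """
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    n = len(ordered)
    resolved: dict[int, str] = {}
    warnings: list[str] = []
    for i, ann in enumerate(ordered):
        if ann.name not in AMBIGUOUS:
            continue
        prev_name = ordered[(i - 1) % n].name if n > 1 else None
        next_name = ordered[(i + 1) % n].name if n > 1 else None
        name = _PREV_RULES[ann.name].get(prev_name) or _NEXT_RULES[ann.name].get(
            next_name
        )
        if name is None:
            warnings.append(
                f"could not resolve ambiguous label {ann.source_label!r} "
                f"at {ann.start}..{ann.end} by syntenic position; dropped"
            )
        resolved[i] = name
    out: list[GeneAnnotation] = []
    for i, ann in enumerate(ordered):
        if i in resolved:
            if resolved[i] is None:
                continue
            ann = dataclasses.replace(ann, name=resolved[i])
        out.append(ann)
    return out, warnings


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {
    "gene", "CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature",
}


def _feature_label(feat: SeqFeature) -> str | None:
    if feat.type == "D-loop":
        return feat.qualifiers.get("note", ["D-loop"])[0] or "D-loop"
    if feat.type == "rep_origin":
        return LIGHT_STRAND_ORIGIN
    for key in ("product", "gene", "standard_name", "note"):
        if key in feat.qualifiers and feat.qualifiers[key]:
            return feat.qualifiers[key][0]
    return None


def _feature_span(feat: SeqFeature, genome_length: int) -> tuple[int, int, int]:
    loc = feat.location
    strand = -1 if loc.strand == -1 else 1
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    if len(parts) == 2:
        # join(x..L, 1..y): a feature wrapping the circular origin.
        (p1, p2) = sorted(parts, key=lambda p: int(p.start))
        if int(p2.end) == genome_length and int(p1.start) == 0:
            return int(p2.start) + 1, int(p1.end), strand
    return int(loc.start) + 1, int(loc.end), strand


def _merge_gene_cds(raw: list[tuple[str, GeneAnnotation]]) -> list[GeneAnnotation]:
    """Merge per-locus 'gene' and 'CDS/tRNA/rRNA' features (CDS wins coords)."""
    out: list[GeneAnnotation] = []
    gene_only: dict[tuple[str, int], GeneAnnotation] = {}
    specific_keys: set[tuple[str, int]] = set()
    for ftype, ann in raw:
        key = (ann.name, ann.strand)
        if ftype == "gene":
            gene_only.setdefault(key, ann)
        else:
            out.append(ann)
            specific_keys.add(key)
    for key, ann in gene_only.items():
        if key not in specific_keys:
            out.append(ann)
    return sorted(out, key=lambda a: (a.start, a.end))


def _taxon_order(taxonomy: list[str]) -> str:
    if "Mammalia" in taxonomy:
        i = taxonomy.index("Mammalia")
        if i + 1 < len(taxonomy):
            return taxonomy[i + 1]
    return taxonomy[-1] if taxonomy else ""


def _convert_seqrecord(rec: SeqRecord) -> MitogenomeRecord:
    try:
        sequence = str(rec.seq).upper()
    except Exception as exc:  # undefined sequence
        raise GenBankParseError(f"{rec.id}: record without sequence") from exc
    if not sequence:
        raise GenBankParseError(f"{rec.id}: record without sequence")

    warnings: list[str] = []
    raw: list[tuple[str, GeneAnnotation]] = []
    for feat in rec.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        label = _feature_label(feat)
        if label is None:
            warnings.append(f"{feat.type} feature at {feat.location} has no label")
            continue
        try:
            name = normalize_gene_name(label)
        except UnmappableLabel:
            warnings.append(f"unmappable label {label!r} ({feat.type} at {feat.location})")
            continue
        start, end, strand = _feature_span(feat, len(sequence))
        raw.append((feat.type, GeneAnnotation(name, start, end, strand, label)))

    annotations = _merge_gene_cds(raw)
    annotations, amb_warnings = resolve_ambiguous_paralogs(annotations)
    warnings.extend(amb_warnings)
    if not annotations:
        warnings.append("empty feature table: record has zero annotations")

    return MitogenomeRecord(
        accession=rec.id or rec.name,
        organism=rec.annotations.get("organism", rec.description or ""),
        taxon_order=_taxon_order(rec.annotations.get("taxonomy", [])),
        sequence=sequence,
        annotations=annotations,
        declared_complete="complete genome" in (rec.description or "").lower(),
        parse_warnings=warnings,
    )


def parse_genbank(path: str | Path) -> list[MitogenomeRecord]:
    """Parse a GenBank flat file (single- or multi-record)."""
    path = Path(path)
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"{path}: malformed GenBank file: {exc}") from exc
    if not seqrecords:
        raise GenBankParseError(f"{path}: no GenBank records found")
    return [_convert_seqrecord(r) for r in seqrecords]


def parse_genbank_dir(directory: str | Path, pattern: str = "*.gb") -> list[MitogenomeRecord]:
    """Parse every GenBank file matching ``pattern`` under a directory."""
    records: list[MitogenomeRecord] = []
    for path in sorted(Path(directory).glob(pattern)):
        records.extend(parse_genbank(path))
    return records


# ---------------------------------------------------------------------------
# GenBank writing
# ---------------------------------------------------------------------------

def _annotation_to_feature(ann: GeneAnnotation, genome_length: int) -> SeqFeature:
    strand = ann.strand
    if ann.start <= ann.end:
        loc = SimpleLocation(ann.start - 1, ann.end, strand=strand)
    else:
        parts = [
            SimpleLocation(ann.start - 1, genome_length, strand=strand),
            SimpleLocation(0, ann.end, strand=strand),
        ]
        if strand == -1:
            parts = parts[::-1]
        loc = CompoundLocation(parts, operator="join")

    if ann.name in TRNA_GENES:
        return SeqFeature(loc, type="tRNA",
                          qualifiers={"product": [TRNA_PRODUCTS[ann.name]]})
    if ann.name in RRNA_GENES:
        product = "12S ribosomal RNA" if ann.name == "rrnS" else "16S ribosomal RNA"
        return SeqFeature(loc, type="rRNA", qualifiers={"product": [product]})
    if ann.name in PROTEIN_GENES:
        return SeqFeature(loc, type="CDS",
                          qualifiers={"gene": [PROTEIN_LABELS[ann.name]],
                                      "transl_table": ["2"]})
    if ann.name == CONTROL_REGION:
        return SeqFeature(loc, type="D-loop",
                          qualifiers={"note": ["control region"]})
    if ann.name == LIGHT_STRAND_ORIGIN:
        return SeqFeature(loc, type="rep_origin",
                          qualifiers={"note": ["origin of L-strand replication"]})
    return SeqFeature(loc, type="misc_feature", qualifiers={"note": [ann.name]})


def to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession[:16],
        description=f"{record.organism} mitochondrion, "
        + ("complete genome" if record.declared_complete else "partial genome"),
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    rec.annotations["data_file_division"] = "MAM"
    rec.annotations["date"] = "15-SEP-2017"  # fixed for byte-identical output
    rec.annotations["organism"] = record.organism
    rec.annotations["taxonomy"] = ["Mammalia", record.taxon_order]
    rec.features.append(
        SeqFeature(SimpleLocation(0, record.length, strand=1), type="source",
                   qualifiers={"organism": [record.organism],
                               "organelle": ["mitochondrion"]})
    )
    for ann in record.sorted_annotations():
        rec.features.append(_annotation_to_feature(ann, record.length))
    return rec


def write_genbank(records: MitogenomeRecord | list[MitogenomeRecord],
                  path: str | Path) -> None:
    """Write one or more records to a GenBank flat file."""
    if isinstance(records, MitogenomeRecord):
        records = [records]
    SeqIO.write([to_seqrecord(r) for r in records], str(Path(path)), "genbank")


# ---------------------------------------------------------------------------
# Plain-text fixture input: TSV annotation table + FASTA genome
# ---------------------------------------------------------------------------

def parse_annotation_table(tsv_path: str | Path, fasta_path: str | Path,
                           taxon_order: str = "") -> list[MitogenomeRecord]:
    """Read records from a TSV table (accession, gene, start, end, strand)
    plus a FASTA file of genome sequences keyed by accession."""
    genomes = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    per_acc: dict[str, list[GeneAnnotation]] = {}
    warnings: dict[str, list[str]] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("accession\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise GenBankParseError(f"{tsv_path}:{lineno}: expected 5 columns")
            acc, label, start, end, strand = fields[:5]
            try:
                name = normalize_gene_name(label)
            except UnmappableLabel:
                warnings.setdefault(acc, []).append(f"unmappable label {label!r}")
                continue
            per_acc.setdefault(acc, []).append(
                GeneAnnotation(name, int(start), int(end),
                               -1 if strand in ("-", "minus", "-1") else 1, label)
            )
    records = []
    for acc, anns in per_acc.items():
        if acc not in genomes:
            raise GenBankParseError(f"{tsv_path}: no FASTA sequence for {acc}")
        anns, amb = resolve_ambiguous_paralogs(anns)
        records.append(
            MitogenomeRecord(acc, acc, taxon_order, genomes[acc], anns,
                             parse_warnings=warnings.get(acc, []) + amb)
        )
    return records
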