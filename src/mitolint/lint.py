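"""Orchestration: run every check over a corpus and summarize per taxon.

The composition per record is deterministic: encode the gene order →
compare it to the auto-selected reference arrangement (marsupial for the
seven marsupial orders, ancestral otherwise; overridable) → verify each
differing gene's orientation against neighbor orthologs → run tRNA
structure checks on all tRNAs → run completeness checks.  Each deviation
yields exactly one finding carrying its verdict and evidence.

The summary mirrors the per-taxon accounting used for the 304-genome
survey: species count, genes differing in arrangement, confirmed vs
refuted, endpoint errors, genes present but unannotated, genes or CR
with missing sequence.  UNRESOLVED verdicts are tallied separately and
excluded from the confirmed/refuted split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import findings as F
from .arrangement import (
    ANCESTRAL_MAMMAL,
    GeneArrangement,
    MARSUPIAL,
    compare_arrangement,
    encode_arrangement,
    reference_for,
)
from .completeness import (
    CompletenessConfig,
    check_complement,
    check_control_region,
    scan_unannotated,
)
from .gene_names import TRNA_GENES
from .genome_io import MitogenomeRecord, extract_gene_sequence
from .orientation import (
    NeighborCache,
    VerificationConfig,
    choose_neighbors,
    verify_orientation,
)
from .structure import ENDPOINT_SUSPECT, LONG_GENE, SHORT_GENE, StructureConfig, check_trna

_VERDICT_TO_CLASS = {
    "CONFIRMED": F.ARRANGEMENT_CONFIRMED,
    "STRAND_ERROR": F.STRAND_ERROR,
    "UNRESOLVED": F.UNRESOLVED,
}


@dataclass(frozen=True)
class LintConfig:
    """Bundle of per-check configurations plus reference selection."""

    reference: str = "auto"  # "auto" | "ancestral" | "marsupial"
    verification: VerificationConfig = field(default_factory=VerificationConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    completeness: CompletenessConfig = field(default_factory=CompletenessConfig)

    def reference_arrangement(self, taxon_order: str) -> GeneArrangement:
        if self.reference == "ancestral":
            return ANCESTRAL_MAMMAL
        if self.reference == "marsupial":
            return MARSUPIAL
        return reference_for(taxon_order)


def _ortholog_lengths(record: MitogenomeRecord, corpus: list[MitogenomeRecord],
                      gene: str) -> list[int]:
    same_order = [
        r for r in corpus
        if r.accession != record.accession and r.taxon_order == record.taxon_order
    ] or [r for r in corpus if r.accession != record.accession]
    lengths = []
    for r in same_order:
        ann = r.get(gene)
        if ann is not None:
            lengths.append(ann.length(r.length))
    return lengths


def lint_record(
    record: MitogenomeRecord,
    corpus: list[MitogenomeRecord],
    config: LintConfig = LintConfig(),
    cache: NeighborCache | None = None,
) -> list[F.LintFinding]:
    """Run all checks on one record against a (possibly empty) corpus."""
    cache = cache or NeighborCache()
    out: list[F.LintFinding] = []
    reference = config.reference_arrangement(record.taxon_order)
    vconf = config.verification

    # 1. gene order vs reference, with orientation verification
    arr = encode_arrangement(record)
    diff = compare_arrangement(arr, reference)
    for gene, ref_idx, obs_idx, ref_sign, obs_sign in diff.differing:
        ann = record.get(gene)
        seq = extract_gene_sequence(record, ann)
        neighbors = choose_neighbors(record, corpus, gene, vconf, cache)
        if neighbors:
            verdict = verify_orientation(seq, neighbors, vconf, gene=gene)
            identity_fwd, identity_rc = verdict.identity_fwd, verdict.identity_rc
            cls = _VERDICT_TO_CLASS[verdict.verdict]
            used = ";".join(verdict.neighbors)
        else:
            identity_fwd = identity_rc = float("nan")
            cls = F.UNRESOLVED
            used = ""
        out.append(
            F.LintFinding(
                record.accession, gene, cls,
                evidence=(
                    f"arrangement deviates from reference "
                    f"(index {ref_idx}->{obs_idx}, "
                    f"sign {'+' if ref_sign > 0 else '-'}->"
                    f"{'+' if obs_sign > 0 else '-'}); "
                    f"identity fwd={identity_fwd:.2f} rc={identity_rc:.2f}"
                ),
                data={
                    "start": ann.start, "end": ann.end,
                    "strand": "+" if ann.strand > 0 else "-",
                    "ref_index": ref_idx, "obs_index": obs_idx,
                    "identity_fwd": round(identity_fwd, 4),
                    "identity_rc": round(identity_rc, 4),
                    "neighbors": used,
                },
            )
        )

    # 2. tRNA structure checks
    for ann in record.sorted_annotations():
        if ann.name not in TRNA_GENES:
            continue
        seq = extract_gene_sequence(record, ann)
        result = check_trna(ann, seq, _ortholog_lengths(record, corpus, ann.name),
                            config.structure)
        base_data = {
            "start": ann.start, "end": ann.end,
            "strand": "+" if ann.strand > 0 else "-",
            "length": result.length, "stem_score": result.stem_score,
        }
        if SHORT_GENE in result.flags:
            out.append(F.LintFinding(
                record.accession, ann.name, F.SHORT_GENE,
                evidence=f"{result.length} nt is below the functional minimum "
                         f"({config.structure.min_trna_len} nt)",
                data=base_data))
        if LONG_GENE in result.flags:
            out.append(F.LintFinding(
                record.accession, ann.name, F.LONG_GENE,
                evidence=f"{result.length} nt exceeds the plausible maximum "
                         f"({config.structure.max_trna_len} nt)",
                data=base_data))
        if ENDPOINT_SUSPECT in result.flags:
            out.append(F.LintFinding(
                record.accession, ann.name, F.ENDPOINT_ERROR,
                evidence=f"acceptor stem scores {result.stem_score}/7 or length "
                         f"{result.length} nt deviates from orthologs",
                data=base_data))

    # 3. completeness
    reference_full = config.reference_arrangement(record.taxon_order)
    out.extend(scan_unannotated(record, corpus, reference_full, vconf,
                                config.completeness, cache))
    recovered = {f.gene for f in out if f.error_class == F.MISSING_ANNOTATION}
    for gene in check_complement(record):
        if gene in recovered:
            continue
        out.append(F.LintFinding(
            record.accession, gene, F.MISSING_SEQUENCE,
            evidence=f"{gene} is not annotated and no unannotated span "
                     f"matches its orthologs",
            data={}))
    out.extend(check_control_region(record, config.completeness,
                                    config.structure.min_trna_len, corpus, vconf))

    return sorted(out, key=lambda f: f.sort_key())


def lint_corpus(records: list[MitogenomeRecord],
                config: LintConfig = LintConfig()) -> list[F.LintFinding]:
    """Lint every record, sharing one neighbor cache across the corpus."""
    cache = NeighborCache()
    out: list[F.LintFinding] = []
    for record in sorted(records, key=lambda r: r.accession):
        out.extend(lint_record(record, records, config, cache))
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "taxon_order", "n_species", "n_genes_differing", "n_confirmed",
    "n_refuted", "n_unresolved", "n_endpoint", "n_unannotated", "n_missing",
]

_CLASS_TO_COLUMN = {
    F.ARRANGEMENT_CONFIRMED: "n_confirmed",
    F.STRAND_ERROR: "n_refuted",
    F.UNRESOLVED: "n_unresolved",
    F.ENDPOINT_ERROR: "n_endpoint",
    F.MISSING_ANNOTATION: "n_unannotated",
    F.MISSING_SEQUENCE: "n_missing",
}


def summarize(findings: list[F.LintFinding],
              records: list[MitogenomeRecord]) -> pd.DataFrame:
    """Per-taxon-order summary with a totals row.

    ``n_genes_differing = n_confirmed + n_refuted + n_unresolved`` by
    construction; SHORT/LONG gene and CR_UNANNOTATED findings are carried
    in the findings table but not tallied here.
    """
    order_of = {r.accession: r.taxon_order for r in records}
    rows: dict[str, dict] = {}
    for r in records:
        row = rows.setdefault(
            r.taxon_order, {c: 0 for c in SUMMARY_COLUMNS[1:]} | {"taxon_order": r.taxon_order}
        )
        row["n_species"] += 1
    for f in findings:
        col = _CLASS_TO_COLUMN.get(f.error_class)
        if col is None:
            continue
        row = rows.get(order_of.get(f.accession, ""))
        if row is None:
            continue
        row[col] += 1
        if col in ("n_confirmed", "n_refuted", "n_unresolved"):
            row["n_genes_differing"] += 1
    df = pd.DataFrame(
        [rows[k] for k in sorted(rows)], columns=SUMMARY_COLUMNS
    )
    if len(df):
        total = df[SUMMARY_COLUMNS[1:]].sum()
        total["taxon_order"] = "Total"
        df = pd.concat([df, pd.DataFrame([total])[SUMMARY_COLUMNS]],
                       ignore_index=True)
    else:
        df = pd.DataFrame([{c: 0 for c in SUMMARY_COLUMNS[1:]}
                           | {"taxon_order": "Total"}], columns=SUMMARY_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "accession", "gene", "error_class", "start", "end", "strand", "length",
    "stem_score", "identity_fwd", "identity_rc", "neighbors", "evidence",
]


def findings_to_tsv(findings: list[F.LintFinding]) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for f in sorted(findings, key=lambda x: x.sort_key()):
        row = {"accession": f.accession, "gene": f.gene,
               "error_class": f.error_class, "evidence": f.evidence}
        row.update({k: f.data[k] for k in f.data if k in _TSV_COLUMNS})
        lines.append("\t".join(str(row.get(c, "")) for c in _TSV_COLUMNS))
    return "\n".join(lines) + "\n"


def findings_to_json(findings: list[F.LintFinding],
                     config: LintConfig = LintConfig()) -> str:
    payload = {
        "config": {
            "reference": config.reference,
            "verification": asdict(config.verification),
            "structure": asdict(config.structure),
            "completeness": asdict(config.completeness),
        },
        "findings": [
            {"accession": f.accession, "gene": f.gene,
             "error_class": f.error_class, "evidence": f.evidence,
             "data": dict(f.data)}
            for f in sorted(findings, key=lambda x: x.sort_key())
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def summary_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False)
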