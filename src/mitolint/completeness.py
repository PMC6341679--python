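"""Missing-annotation and missing-sequence detection.

Two distinct failure modes hide in "complete" database records: a gene
whose sequence is present but was never annotated, and sequence that is
simply absent although the record claims completeness.  The second
concentrates in the trnT–trnP–CR–trnF–rrnS stretch: the control region
resists PCR and sequencing, so truncated assemblies tend to lose the CR
together with parts of its flanking tRNAs.

The gap scanner recovers unannotated genes by asking, for every sizeable
inter-annotation gap, which gene the reference arrangement expects at that
syntenic position, then aligning the gap against neighbor orthologs of
that gene in both orientations under the 80% rule.  The control region is
held to a much looser 50% identity standard — it evolves fast, and even
congeneric D-loops can drop towards 57% identity.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import findings as F
from .arrangement import GeneArrangement
from .gene_names import ALL_GENES, CONTROL_REGION
from .genome_io import GeneAnnotation, MitogenomeRecord, extract_gene_sequence, revcomp
from .orientation import NeighborCache, VerificationConfig, choose_neighbors, global_align_identity


@dataclass(frozen=True)
class CompletenessConfig:
    min_cr_len: int = 200
    min_gap_scan_len: int = 30
    cr_identity_threshold: float = 0.50

    def __post_init__(self) -> None:
        if min(self.min_cr_len, self.min_gap_scan_len) <= 0:
            raise ValueError("lengths must be positive")
        if self.cr_identity_threshold <= 0:
            raise ValueError("cr_identity_threshold must be positive")


def check_complement(record: MitogenomeRecord) -> list[str]:
    """Canonical genes absent from the record's annotation (CR excluded)."""
    annotated = {a.name for a in record.annotations}
    return [g for g in ALL_GENES if g not in annotated]


# ---------------------------------------------------------------------------
# gap geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gap:
    prev: GeneAnnotation
    next: GeneAnnotation
    start: int  # 1-based, may exceed genome length (unrolled circle)
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def annotation_gaps(record: MitogenomeRecord) -> list[Gap]:
    """Inter-annotation gaps along the circle (unrolled coordinates)."""
    anns = record.sorted_annotations()
    if len(anns) < 2:
        return []
    L = record.length
    gaps = []
    for i, ann in enumerate(anns):
        nxt = anns[(i + 1) % len(anns)]
        end_here = ann.unrolled_end(L)
        next_start = nxt.start if i + 1 < len(anns) else nxt.start + L
        if next_start - end_here - 1 > 0:
            gaps.append(Gap(ann, nxt, end_here + 1, next_start - 1))
    return gaps


def _gap_sequence(record: MitogenomeRecord, gap: Gap) -> str:
    L = record.length
    s = (gap.start - 1) % L
    e = (gap.end - 1) % L
    if s <= e:
        return record.sequence[s : e + 1]
    return record.sequence[s:] + record.sequence[: e + 1]


def _flanker_state(record: MitogenomeRecord, name: str, min_len: int) -> str:
    ann = record.get(name)
    if ann is None:
        return "absent"
    if ann.length(record.length) < min_len:
        return "truncated"
    return "intact"


# ---------------------------------------------------------------------------
# control region
# ---------------------------------------------------------------------------

def check_control_region(
    record: MitogenomeRecord,
    config: CompletenessConfig = CompletenessConfig(),
    min_trna_len: int = 55,
    corpus: list[MitogenomeRecord] | None = None,
    vconfig: VerificationConfig | None = None,
) -> list[F.LintFinding]:
    """Flag missing or unannotated control-region sequence.

    CR length is the annotated CR span or, failing that, the unassigned
    nucleotides between trnP and trnF.  MISSING_SEQUENCE fires on a
    zero-length CR, or on a short CR corroborated by a truncated/absent
    flanking tRNA; CR_UNANNOTATED fires on an unannotated span that is
    long enough to be a real control region.
    """
    out: list[F.LintFinding] = []
    L = record.length
    cr = record.get(CONTROL_REGION)
    flankers = {g: _flanker_state(record, g, min_trna_len) for g in ("trnT", "trnP", "trnF")}
    damaged = [g for g, st in flankers.items() if st != "intact"]

    if cr is not None:
        cr_len = cr.length(L)
        span_start, span_end = cr.start, cr.end
        annotated = True
    else:
        trnP, trnF = record.get("trnP"), record.get("trnF")
        if trnP is None or trnF is None:
            cr_len = 0
            span_start = span_end = 0
        else:
            end_p = trnP.unrolled_end(L)
            start_f = trnF.start if trnF.start > end_p % L or trnF.start > trnP.start else trnF.start + L
            if start_f <= end_p:
                start_f += L
            cr_len = start_f - end_p - 1
            span_start = (end_p % L) + 1
            span_end = ((start_f - 1 - 1) % L) + 1
        annotated = False

    data = {
        "cr_length": cr_len,
        "start": span_start,
        "end": span_end,
        "flanking_trnas": ";".join(f"{g}={st}" for g, st in flankers.items()),
    }

    if cr_len == 0 or (cr_len < config.min_cr_len and damaged):
        out.append(
            F.LintFinding(
                record.accession, CONTROL_REGION, F.MISSING_SEQUENCE,
                evidence=(
                    f"control region length {cr_len} nt"
                    + (f"; damaged flankers: {','.join(damaged)}" if damaged else "")
                ),
                data=data,
            )
        )
    elif not annotated and cr_len >= config.min_cr_len:
        evidence = f"unannotated {cr_len}-nt span between trnP and trnF"
        if corpus:
            ident = _best_cr_identity(record, span_start, span_end, corpus,
                                      vconfig or VerificationConfig())
            if ident is not None:
                data = {**data, "identity": round(ident, 4)}
                evidence += f"; identity to neighbor CR {ident:.2f}"
        out.append(
            F.LintFinding(record.accession, CONTROL_REGION, F.CR_UNANNOTATED,
                          evidence=evidence, data=data)
        )
    return out


def _best_cr_identity(record, span_start, span_end, corpus, vconfig) -> float | None:
    gap = Gap(GeneAnnotation("trnP", 0, 0, 1), GeneAnnotation("trnF", 0, 0, 1),
              span_start, span_end if span_end >= span_start else span_end + record.length)
    seq = _gap_sequence(record, gap)
    best = None
    for other in corpus:
        if other.accession == record.accession:
            continue
        cr = other.get(CONTROL_REGION)
        if cr is None:
            continue
        ident = global_align_identity(seq, extract_gene_sequence(other, cr), vconfig)
        best = ident if best is None else max(best, ident)
    return best


# ---------------------------------------------------------------------------
# unannotated-gene recovery
# ---------------------------------------------------------------------------

def _expected_between(reference: GeneArrangement, prev: str, nxt: str) -> list[str]:
    """Genes the reference expects strictly between prev and nxt."""
    names = list(reference.names)
    if prev not in names or nxt not in names:
        return []
    n = len(names)
    i = names.index(prev)
    expected = []
    j = (i + 1) % n
    while names[j] != nxt and len(expected) < n:
        expected.append(names[j])
        j = (j + 1) % n
    return expected if names[j] == nxt else []


def scan_unannotated(
    record: MitogenomeRecord,
    corpus: list[MitogenomeRecord],
    reference: GeneArrangement,
    vconfig: VerificationConfig = VerificationConfig(),
    config: CompletenessConfig = CompletenessConfig(),
    cache: NeighborCache | None = None,
) -> list[F.LintFinding]:
    """Recover genes present in sequence but absent from the annotation.

    Every inter-annotation gap of at least ``min_gap_scan_len`` nt —
    excluding the control-region locus (trnP→trnF) and the light-strand
    origin locus (trnN→trnC) — is matched to the genes the reference
    arrangement expects there, then aligned against neighbor orthologs of
    those genes in both orientations.
    """
    cache = cache or NeighborCache()
    out: list[F.LintFinding] = []
    L = record.length
    anns = record.sorted_annotations()
    ref_names = set(reference.names)

    def nearest_gene(start_ann, step: int) -> str | None:
        """Nearest flanking annotation that is a gene of the reference,
        walking outward past CR/OL."""
        i = anns.index(start_ann)
        for k in range(len(anns)):
            name = anns[(i + step * k) % len(anns)].name
            if name in ref_names:
                return name
        return None

    for gap in annotation_gaps(record):
        if gap.length < config.min_gap_scan_len:
            continue
        prev_name, next_name = gap.prev.name, gap.next.name
        if {prev_name, next_name} == {"trnP", "trnF"}:
            continue  # unannotated CR locus; handled by check_control_region
        if {prev_name, next_name} == {"trnN", "trnC"}:
            continue  # unannotated OL locus
        prev_gene = nearest_gene(gap.prev, -1)
        next_gene = nearest_gene(gap.next, +1)
        if prev_gene is None or next_gene is None:
            continue
        annotated = {a.name for a in record.annotations}
        expected = [
            g for g in _expected_between(reference, prev_gene, next_gene)
            if g not in annotated
        ]
        if not expected:
            continue
        gap_seq = _gap_sequence(record, gap)
        for gene in expected:
            neighbors = choose_neighbors(record, corpus, gene, vconfig, cache)
            if not neighbors:
                continue
            id_fwd = max(global_align_identity(gap_seq, s, vconfig) for _, s in neighbors)
            id_rc = max(
                global_align_identity(revcomp(gap_seq), s, vconfig) for _, s in neighbors
            )
            best = max(id_fwd, id_rc)
            if best >= vconfig.identity_threshold:
                strand = "+" if id_fwd >= id_rc else "-"
                out.append(
                    F.LintFinding(
                        record.accession, gene, F.MISSING_ANNOTATION,
                        evidence=(
                            f"{gene} not annotated but gap "
                            f"{(gap.start - 1) % L + 1}..{(gap.end - 1) % L + 1} "
                            f"matches orthologs at identity {best:.2f} "
                            f"on strand {strand}"
                        ),
                        data={
                            "start": (gap.start - 1) % L + 1,
                            "end": (gap.end - 1) % L + 1,
                            "strand": strand,
                            "identity_fwd": round(id_fwd, 4),
                            "identity_rc": round(id_rc, 4),
                            "neighbors": ";".join(a for a, _ in neighbors),
                        },
                    )
                )
    return out
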