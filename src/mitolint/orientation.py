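"""Both-orientation ortholog alignment: the 80%-identity strand check.

For each gene annotated in an arrangement that deviates from the
reference, the gene sequence *as annotated* is globally aligned against
orthologs from closely related species in both orientations.  If the
annotated orientation reaches the identity threshold (default 0.80) the
rearrangement is confirmed; if only the reverse complement does, the
annotation is a strand error; if neither does, the case is unresolved.

Identity is computed over alignment columns after stripping terminal gap
columns, so a length-discordant annotation (an endpoint error) does not
mask the orientation signal.  N bases never count as identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import MitogenomeRecord, extract_gene_sequence, revcomp

CONFIRMED = "CONFIRMED"
STRAND_ERROR = "STRAND_ERROR"
UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class VerificationConfig:
    """Scoring and thresholds for the both-orientation check.

    ``identity_threshold`` is the paper-operative 80% rule; scoring is a
    simple linear scheme (match +1, mismatch -1, gap -2).
    """

    identity_threshold: float = 0.80
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2
    min_neighbors: int = 1
    max_neighbors: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass(frozen=True)
class OrientationVerdict:
    gene: str
    identity_fwd: float
    identity_rc: float
    verdict: str
    neighbors: tuple[str, ...] = ()


@lru_cache(maxsize=8)
def _aligner(match: int, mismatch: int, gap: int) -> PairwiseAligner:
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            mat[x, y] = match if x == y else mismatch
    for x in "ACGTN":
        mat[x, "N"] = mismatch
        mat["N", x] = mismatch
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


_NON_ACGT = re.compile(r"[^ACGT]")


def _sanitize(seq: str) -> str:
    return _NON_ACGT.sub("N", seq.upper())


def global_align_identity(
    query: str, ref: str, config: VerificationConfig = VerificationConfig()
) -> float:
    """Fractional identity of the optimal global alignment of two sequences.

    The denominator counts all alignment columns between the first and last
    aligned pair (i.e. terminal gap columns are stripped; internal gaps
    count).  The numerator counts columns with identical A/C/G/T bases.
    """
    if not query or not ref:
        raise ValueError("global_align_identity requires non-empty sequences")
    q, r = _sanitize(query), _sanitize(ref)
    aligner = _aligner(config.match_score, config.mismatch_score, config.gap_score)
    alignment = aligner.align(q, r)[0]
    blocks_q, blocks_r = alignment.aligned
    if len(blocks_q) == 0:
        return 0.0
    aligned_pairs = sum(int(qe - qs) for qs, qe in blocks_q)
    q_span = int(blocks_q[-1][1]) - int(blocks_q[0][0])
    r_span = int(blocks_r[-1][1]) - int(blocks_r[0][0])
    columns = aligned_pairs + (q_span - aligned_pairs) + (r_span - aligned_pairs)
    identical = 0
    for (qs, qe), (rs, _) in zip(blocks_q, blocks_r):
        for off in range(int(qe) - int(qs)):
            cq = q[int(qs) + off]
            if cq != "N" and cq == r[int(rs) + off]:
                identical += 1
    return identical / columns if columns else 0.0


def verify_orientation(
    gene_seq_as_annotated: str,
    neighbor_orthologs: list[str] | list[tuple[str, str]],
    config: VerificationConfig = VerificationConfig(),
    gene: str = "",
) -> OrientationVerdict:
    """Decide whether an annotated gene orientation is supported.

    ``neighbor_orthologs`` holds ortholog sequences in functional
    orientation, optionally as (accession, sequence) pairs.  Decision:
    fwd ≥ τ and fwd > rc → CONFIRMED; rc ≥ τ and rc > fwd → STRAND_ERROR;
    an exact fwd = rc tie, or both below τ → UNRESOLVED.
    """
    if not neighbor_orthologs:
        raise ValueError("verify_orientation requires at least one neighbor")
    if isinstance(neighbor_orthologs[0], tuple):
        accessions = tuple(a for a, _ in neighbor_orthologs)
        seqs = [s for _, s in neighbor_orthologs]
    else:
        accessions = ()
        seqs = list(neighbor_orthologs)

    rc_seq = revcomp(gene_seq_as_annotated)
    identity_fwd = max(global_align_identity(gene_seq_as_annotated, s, config) for s in seqs)
    identity_rc = max(global_align_identity(rc_seq, s, config) for s in seqs)

    tau = config.identity_threshold
    if identity_fwd >= tau and identity_fwd > identity_rc:
        verdict = CONFIRMED
    elif identity_rc >= tau and identity_rc > identity_fwd:
        verdict = STRAND_ERROR
    else:
        verdict = UNRESOLVED
    return OrientationVerdict(gene, identity_fwd, identity_rc, verdict, accessions)


class NeighborCache:
    """Memoizes anchor-gene identities between record pairs within one run."""

    def __init__(self) -> None:
        self._identity: dict[frozenset, float] = {}

    def anchor_identity(
        self,
        a: MitogenomeRecord,
        b: MitogenomeRecord,
        config: VerificationConfig,
        anchor_gene: str = "cox1",
    ) -> float:
        key = frozenset((a.accession, b.accession))
        if key not in self._identity:
            ann_a, ann_b = a.get(anchor_gene), b.get(anchor_gene)
            if ann_a is None or ann_b is None:
                self._identity[key] = 0.0
            else:
                self._identity[key] = global_align_identity(
                    extract_gene_sequence(a, ann_a),
                    extract_gene_sequence(b, ann_b),
                    config,
                )
        return self._identity[key]


def _conforms(rec: MitogenomeRecord, gene: str) -> bool:
    """A donor's annotation of ``gene`` is trustworthy only if it agrees in
    strand with the reference arrangement for the donor's own taxon."""
    from .arrangement import reference_for  # deferred: avoids import cycle

    ann = rec.get(gene)
    if ann is None:
        return False
    ref_sign = reference_for(rec.taxon_order).signs.get(gene)
    return ref_sign is not None and ann.strand == ref_sign


def choose_neighbors(
    record: MitogenomeRecord,
    corpus: list[MitogenomeRecord],
    gene: str,
    config: VerificationConfig = VerificationConfig(),
    cache: NeighborCache | None = None,
) -> list[tuple[str, str]]:
    """Pick up to ``max_neighbors`` ortholog donors for a gene.

    Candidates share the query's taxonomic order (falling back to the whole
    corpus), must have the gene annotated, exclude the query record itself,
    and are ranked by identity of the conserved anchor gene cox1.  Donors
    whose own annotation of the gene deviates in strand from their
    reference arrangement are used only when no conforming donor exists: a
    co-deviating annotation cannot vouch for the annotation under test.
    Returns (accession, ortholog sequence in functional orientation) pairs;
    empty when no candidate exists (the "no-neighbor" signal).
    """
    cache = cache or NeighborCache()

    def eligible(rec: MitogenomeRecord) -> bool:
        return rec.accession != record.accession and rec.get(gene) is not None

    same_order = [r for r in corpus if eligible(r) and r.taxon_order == record.taxon_order]
    anywhere = [r for r in corpus if eligible(r)]
    candidates = next(
        (
            tier
            for tier in (
                [r for r in same_order if _conforms(r, gene)],
                [r for r in anywhere if _conforms(r, gene)],
                same_order,
                anywhere,
            )
            if tier
        ),
        [],
    )
    if not candidates:
        return []
    ranked = sorted(
        candidates,
        key=lambda r: (-cache.anchor_identity(record, r, config), r.accession),
    )
    out = []
    for r in ranked[: config.max_neighbors]:
        ann = r.get(gene)
        out.append((r.accession, extract_gene_sequence(r, ann)))
    return out
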