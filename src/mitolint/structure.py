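"""tRNA plausibility checks: length bounds and the acceptor-stem fold.

Mammalian mitochondrial tRNAs run roughly 59–75 nt (trnS1, which lacks the
D-arm, is the shortest).  A grossly short or long annotation cannot encode
a functional tRNA; a window whose ends cannot form the 7-bp amino-acyl
acceptor stem points at misplaced endpoints.  Only the acceptor stem is
scored — mitochondrial tRNAs have degenerate D- and T-arms, so a full
cloverleaf or covariance model would over-call errors; the stem is the
structural element diagnostic of correct endpoints and orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .gene_names import is_trna
from .genome_io import GeneAnnotation

SHORT_GENE = "SHORT_GENE"
LONG_GENE = "LONG_GENE"
ENDPOINT_SUSPECT = "ENDPOINT_SUSPECT"

# Watson-Crick pairs plus the G·U wobble admissible in RNA helices.
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = _WC_PAIRS | {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class StructureConfig:
    min_trna_len: int = 55
    max_trna_len: int = 90
    min_stem_pairs: int = 5
    ortholog_len_tolerance: int = 10

    def __post_init__(self) -> None:
        if self.min_trna_len >= self.max_trna_len:
            raise ValueError("min_trna_len must be < max_trna_len")
        if not (0 <= self.min_stem_pairs <= 7):
            raise ValueError("min_stem_pairs must be in [0, 7]")


@dataclass(frozen=True)
class TrnaCheckResult:
    gene: str
    length: int
    stem_score: int
    flags: frozenset[str]

    def __post_init__(self) -> None:
        assert not ({SHORT_GENE, LONG_GENE} <= self.flags)


def acceptor_stem_score(seq: str, wobble: bool = True) -> int:
    """Number of paired positions (0–7) in the putative acceptor stem.

    Position i (1..7) is paired when base i and base L−i+1 form a
    Watson–Crick pair or, when ``wobble`` is set, a G·U wobble pair.
    N never pairs.  The gene is scored as annotated: mitochondrial tRNA
    genes do not encode the CCA tail, so nothing is trimmed.
    """
    L = len(seq)
    if L < 14:
        raise ValueError(f"sequence of length {L} too short for a stem check")
    s = seq.upper()
    pairs = _WOBBLE_PAIRS if wobble else _WC_PAIRS
    return sum(1 for i in range(7) if (s[i], s[L - 1 - i]) in pairs)


def check_trna(
    ann: GeneAnnotation,
    seq: str,
    ortholog_lengths: list[int] | None = None,
    config: StructureConfig = StructureConfig(),
) -> TrnaCheckResult:
    """Flag a tRNA annotation that is implausibly sized or cannot fold.

    ``seq`` is the gene sequence in reading orientation.  ENDPOINT_SUSPECT
    fires when the acceptor stem scores below ``min_stem_pairs`` or when
    the length deviates from the ortholog median by more than
    ``ortholog_len_tolerance`` (when ortholog lengths are available).
    """
    if not is_trna(ann.name):
        raise ValueError(f"{ann.name} is not a tRNA gene")
    length = len(seq)
    flags: set[str] = set()
    if length < config.min_trna_len:
        flags.add(SHORT_GENE)
    elif length > config.max_trna_len:
        flags.add(LONG_GENE)
    stem = acceptor_stem_score(seq) if length >= 14 else 0
    if stem < config.min_stem_pairs:
        flags.add(ENDPOINT_SUSPECT)
    if ortholog_lengths:
        if abs(length - median(ortholog_lengths)) > config.ortholog_len_tolerance:
            flags.add(ENDPOINT_SUSPECT)
    return TrnaCheckResult(ann.name, length, stem, frozenset(flags))
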