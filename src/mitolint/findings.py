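"""The finding record shared by all checks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

ARRANGEMENT_CONFIRMED = "ARRANGEMENT_CONFIRMED"
STRAND_ERROR = "STRAND_ERROR"
ENDPOINT_ERROR = "ENDPOINT_ERROR"
MISSING_ANNOTATION = "MISSING_ANNOTATION"
MISSING_SEQUENCE = "MISSING_SEQUENCE"
SHORT_GENE = "SHORT_GENE"
LONG_GENE = "LONG_GENE"
UNRESOLVED = "UNRESOLVED"
CR_UNANNOTATED = "CR_UNANNOTATED"

ERROR_CLASSES = (
    ARRANGEMENT_CONFIRMED,
    STRAND_ERROR,
    ENDPOINT_ERROR,
    MISSING_ANNOTATION,
    MISSING_SEQUENCE,
    SHORT_GENE,
    LONG_GENE,
    UNRESOLVED,
    CR_UNANNOTATED,
)

#: Classes that describe an actual problem (ARRANGEMENT_CONFIRMED does not).
PROBLEM_CLASSES = tuple(c for c in ERROR_CLASSES if c != ARRANGEMENT_CONFIRMED)


@dataclass(frozen=True)
class LintFinding:
    """One detected problem (or confirmation) on one gene of one record.

    ``data`` carries the machine-readable evidence: identities, lengths,
    coordinates — whatever the producing check measured.
    """

    accession: str
    gene: str
    error_class: str
    evidence: str = ""
    data: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.error_class not in ERROR_CLASSES:
            raise ValueError(f"unknown error class {self.error_class!r}")

    @property
    def start(self) -> int:
        return int(self.data.get("start", 0))

    def sort_key(self) -> tuple:
        return (self.accession, self.start, self.gene, self.error_class)
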