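"""Canonical mitochondrial gene vocabulary and label normalization.

The mammalian mitogenome carries a fixed complement of 37 genes — 13
protein-coding genes, 2 rRNAs and 22 tRNAs — plus two noncoding elements,
the control region (CR, containing the D-loop) and the light-strand
replication origin (OL).  GenBank submitters label these genes with a wide
variety of synonyms ("COI", "cytochrome c oxidase subunit 1", "tRNA-Trp",
"12S ribosomal RNA", "A+T-rich region", ...).  This module maps raw labels
onto one closed canonical vocabulary so that downstream gene-order and
completeness checks can rely on exact identifiers.

The leucine and serine tRNAs each occur twice, distinguished by the codon
family they read: trnL1 (CUN), trnL2 (UUR), trnS1 (AGY), trnS2 (UCN).
A bare "tRNA-Leu"/"tRNA-Ser" label is under-specified; normalization then
returns an ambiguity marker which the parser resolves by syntenic position.
"""

from __future__ import annotations

import re

PROTEIN_GENES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

RRNA_GENES = ("rrnS", "rrnL")

TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

#: The 37-gene complement of the mammalian mitochondrial genome.
ALL_GENES = PROTEIN_GENES + RRNA_GENES + TRNA_GENES

#: Noncoding elements tracked alongside genes.
CONTROL_REGION = "CR"
LIGHT_STRAND_ORIGIN = "OL"
NONCODING = (CONTROL_REGION, LIGHT_STRAND_ORIGIN)

#: Markers returned for codon-family-less leucine/serine tRNA labels.
AMBIGUOUS_LEU = "trnL?"
AMBIGUOUS_SER = "trnS?"
AMBIGUOUS = (AMBIGUOUS_LEU, AMBIGUOUS_SER)

VOCABULARY = frozenset(ALL_GENES) | frozenset(NONCODING)


class UnmappableLabel(ValueError):
    """Raised when a raw feature label cannot be mapped onto the vocabulary."""

    def __init__(self, raw_label: str):
        self.raw_label = raw_label
        super().__init__(f"unmappable gene label: {raw_label!r}")


_AA3_TO_TRNA = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD",
    "cys": "trnC", "gln": "trnQ", "glu": "trnE", "gly": "trnG",
    "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "phe": "trnF", "pro": "trnP", "thr": "trnT", "trp": "trnW",
    "tyr": "trnY", "val": "trnV",
    "leu": AMBIGUOUS_LEU, "ser": AMBIGUOUS_SER,
}

_AA1_TO_TRNA = {
    "a": "trnA", "r": "trnR", "n": "trnN", "d": "trnD", "c": "trnC",
    "q": "trnQ", "e": "trnE", "g": "trnG", "h": "trnH", "i": "trnI",
    "k": "trnK", "m": "trnM", "f": "trnF", "p": "trnP", "t": "trnT",
    "w": "trnW", "y": "trnY", "v": "trnV",
    "l": AMBIGUOUS_LEU, "s": AMBIGUOUS_SER,
}

# Codon families distinguishing the leucine/serine paralogs.
_CODON_FAMILY = {
    ("l", "uur"): "trnL2", ("l", "cun"): "trnL1",
    ("s", "ucn"): "trnS2", ("s", "agy"): "trnS1",
    ("l", "1"): "trnL1", ("l", "2"): "trnL2",
    ("s", "1"): "trnS1", ("s", "2"): "trnS2",
}

# Keys are raw labels lowercased with all non-alphanumerics removed.
_SYNONYMS: dict[str, str] = {}


def _add(canonical: str, *labels: str) -> None:
    for label in labels:
        key = re.sub(r"[^a-z0-9]", "", label.lower())
        _SYNONYMS[key] = canonical


_add("cox1", "cox1", "coxi", "coi", "co1", "mtco1", "coxI",
     "cytochrome c oxidase subunit 1", "cytochrome c oxidase subunit I",
     "cytochrome oxidase subunit 1", "cytochrome oxidase subunit I")
_add("cox2", "cox2", "coxii", "coii", "co2", "mtco2",
     "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit II",
     "cytochrome oxidase subunit 2", "cytochrome oxidase subunit II")
_add("cox3", "cox3", "coxiii", "coiii", "co3", "mtco3",
     "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit III",
     "cytochrome oxidase subunit 3", "cytochrome oxidase subunit III")
_add("cob", "cob", "cytb", "cyt b", "mtcyb", "cytochrome b",
     "cytochrome b apoenzyme")
_add("atp6", "atp6", "atpase6", "atpase 6", "atp synthase 6",
     "atp synthase f0 subunit 6", "atpase subunit 6", "mtatp6")
_add("atp8", "atp8", "atpase8", "atpase 8", "atp synthase 8",
     "atp synthase f0 subunit 8", "atpase subunit 8", "mtatp8")
for _i in range(1, 7):
    _add(f"nad{_i}", f"nad{_i}", f"nd{_i}", f"nadh{_i}",
         f"nadh dehydrogenase subunit {_i}", f"mtnd{_i}")
_add("nad4L", "nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l",
     "mtnd4l")
_add("rrnS", "rrns", "12s", "12s rrna", "12s ribosomal rna", "s-rrna",
     "srrna", "small subunit ribosomal rna", "ssu rrna", "mtrnr1", "rnr1",
     "12 s rrna")
_add("rrnL", "rrnl", "16s", "16s rrna", "16s ribosomal rna", "l-rrna",
     "lrrna", "large subunit ribosomal rna", "lsu rrna", "mtrnr2", "rnr2",
     "16 s rrna")
_add(CONTROL_REGION, "cr", "d-loop", "dloop", "d loop", "d-loop region",
     "control region", "a+t-rich region", "at-rich region", "a+t rich region",
     "putative control region", "misc control region")
_add(LIGHT_STRAND_ORIGIN, "ol", "o-l", "oril", "ori-l", "rep origin",
     "origin of l-strand replication", "l-strand replication origin",
     "light strand replication origin", "light-strand origin",
     "origin of light strand replication", "l-strand origin of replication")

# Canonical identifiers map to themselves (case-insensitively).
for _g in ALL_GENES:
    _add(_g, _g)

_TRNA_RE = re.compile(r"^t?rna[\s_-]*([a-z]{3})", re.IGNORECASE)
_TRN_RE = re.compile(r"^trn([a-z])([12]?)$", re.IGNORECASE)
_FAMILY_RE = re.compile(r"\b(uur|cun|ucn|agy|uua|uag|taa|tag|tga|uga|gcu|gct)\b",
                        re.IGNORECASE)

# Anticodon spellings occasionally used instead of codon families.
_ANTICODON_FAMILY = {
    "taa": "uur", "uaa": "uur", "tag": "cun", "uag": "cun",
    "tga": "ucn", "uga": "ucn", "gct": "agy", "gcu": "agy",
}


def _codon_family(text: str) -> str | None:
    m = _FAMILY_RE.search(text.lower())
    if not m:
        return None
    fam = m.group(1)
    return _ANTICODON_FAMILY.get(fam, fam)


def normalize_gene_name(raw_label: str) -> str:
    """Map a raw GenBank feature label to a canonical gene identifier.

    Returns one of the 37 gene ids, ``CR``, ``OL``, or an ambiguity marker
    (:data:`AMBIGUOUS_LEU`/:data:`AMBIGUOUS_SER`) for leucine/serine tRNA
    labels lacking a codon-family qualifier.

    Raises
    ------
    UnmappableLabel
        If the label matches nothing in the synonym table.
    """
    if raw_label is None:
        raise UnmappableLabel(str(raw_label))
    s = raw_label.strip()
    if not s:
        raise UnmappableLabel(raw_label)

    key = re.sub(r"[^a-z0-9]", "", s.lower())
    if key in _SYNONYMS:
        return _SYNONYMS[key]

    # trnX / trnL1-style compact labels, possibly with a codon qualifier.
    m = _TRN_RE.match(re.sub(r"\(.*\)$", "", s).strip())
    if m:
        letter = m.group(1).lower()
        if letter in _AA1_TO_TRNA:
            if m.group(2):
                fam = _CODON_FAMILY.get((letter, m.group(2)))
                if fam:
                    return fam
            base = _AA1_TO_TRNA[letter]
            if base in AMBIGUOUS:
                fam = _codon_family(s)
                if fam:
                    resolved = _CODON_FAMILY.get((letter, fam))
                    if resolved:
                        return resolved
            return base

    # tRNA-Xxx style labels.
    m = _TRNA_RE.match(s)
    if m:
        aa3 = m.group(1).lower()
        if aa3 in _AA3_TO_TRNA:
            base = _AA3_TO_TRNA[aa3]
            if base in AMBIGUOUS:
                fam = _codon_family(s[m.end():])
                if fam:
                    resolved = _CODON_FAMILY.get((base[3].lower(), fam))
                    if resolved:
                        return resolved
            return base

    raise UnmappableLabel(raw_label)


def is_trna(name: str) -> bool:
    """True for canonical tRNA gene identifiers."""
    return name in TRNA_GENES


#: Pretty product labels used when writing GenBank records.
TRNA_PRODUCTS = {
    "trnA": "tRNA-Ala", "trnR": "tRNA-Arg", "trnN": "tRNA-Asn",
    "trnD": "tRNA-Asp", "trnC": "tRNA-Cys", "trnQ": "tRNA-Gln",
    "trnE": "tRNA-Glu", "trnG": "tRNA-Gly", "trnH": "tRNA-His",
    "trnI": "tRNA-Ile", "trnK": "tRNA-Lys", "trnM": "tRNA-Met",
    "trnF": "tRNA-Phe", "trnP": "tRNA-Pro", "trnT": "tRNA-Thr",
    "trnW": "tRNA-Trp", "trnY": "tRNA-Tyr", "trnV": "tRNA-Val",
    "trnL1": "tRNA-Leu (CUN)", "trnL2": "tRNA-Leu (UUR)",
    "trnS1": "tRNA-Ser (AGY)", "trnS2": "tRNA-Ser (UCN)",
}

PROTEIN_LABELS = {
    "atp6": "ATP6", "atp8": "ATP8", "cob": "CYTB",
    "cox1": "COX1", "cox2": "COX2", "cox3": "COX3",
    "nad1": "ND1", "nad2": "ND2", "nad3": "ND3",
    "nad4": "ND4", "nad4L": "ND4L", "nad5": "ND5", "nad6": "ND6",
}

#: Single-token names used in the compact arrangement notation ("-A-CW-N-Y").
COMPACT_TOKENS = {g: g[3:] for g in TRNA_GENES}
COMPACT_TOKENS.update({g: g for g in PROTEIN_GENES + RRNA_GENES})
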