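"""Signed circular gene orders and single-TDRL reachability.

A mitogenome's gene order is modelled as a signed circular permutation of
the 37 canonical gene identifiers (CR and OL are excluded: they are
non-gene features absent from many records).  Arrangements are
rotation-normalized by linearizing at an anchor gene (trnF by default, the
conventional start of vertebrate mitogenome numbering).

Two reference arrangements cover all mammals: the ancestral arrangement
shared by monotremes and eutherians (identical to human mtDNA) and the
marsupial arrangement, which differs only inside the WANCY tRNA cluster
(W -A -N -C -Y rearranged to -A -C W -N -Y).  The marsupial order is
reachable from the ancestral one by a single tandem duplication/random
loss (TDRL) event: a contiguous block is duplicated in tandem and exactly
one copy of each duplicated gene is subsequently lost.  TDRL preserves
strand, so any sign change rules the model out.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_names import (
    ALL_GENES,
    COMPACT_TOKENS,
    NONCODING,
)

Signed = tuple[str, int]


class DuplicateGeneError(ValueError):
    pass


@dataclass(frozen=True)
class GeneArrangement:
    """A signed circular permutation of canonical gene ids.

    ``genes`` is the linearization beginning at ``anchor`` (or, if the
    anchor is absent, at the fallback gene recorded in ``anchor``).
    """

    genes: tuple[Signed, ...]
    anchor: str = "trnF"

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateGeneError(f"duplicate gene ids in arrangement: {dupes}")
        for g in names:
            if g in NONCODING:
                raise ValueError(f"{g} is not part of a gene arrangement")

    @classmethod
    def from_pairs(cls, pairs, anchor: str = "trnF") -> "GeneArrangement":
        """Build from (gene, sign) pairs, rotating to the anchor if present."""
        pairs = tuple((g, 1 if s >= 0 else -1) for g, s in pairs)
        names = [g for g, _ in pairs]
        if anchor in names:
            i = names.index(anchor)
            pairs = pairs[i:] + pairs[:i]
        return cls(pairs, anchor=anchor)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    @property
    def signs(self) -> dict[str, int]:
        return dict(self.genes)

    def index(self) -> dict[str, int]:
        return {g: i for i, (g, _) in enumerate(self.genes)}

    def restricted(self, universe) -> "GeneArrangement":
        """Arrangement restricted to a gene subset, order preserved."""
        kept = tuple(p for p in self.genes if p[0] in universe)
        anchor = self.anchor if self.anchor in universe else (kept[0][0] if kept else self.anchor)
        return GeneArrangement.from_pairs(kept, anchor=anchor)

    def rotated_to(self, gene: str) -> "GeneArrangement":
        return GeneArrangement.from_pairs(self.genes, anchor=gene)

    def notation(self) -> str:
        """Compact notation: single-letter tRNA codes, '-' for minus strand."""
        return "".join(
            ("-" if s < 0 else "") + COMPACT_TOKENS.get(g, g) for g, s in self.genes
        )

    def __len__(self) -> int:
        return len(self.genes)


# --- packaged reference arrangements ---------------------------------------

ANCESTRAL_MAMMAL = GeneArrangement.from_pairs([
    ("trnF", 1), ("rrnS", 1), ("trnV", 1), ("rrnL", 1), ("trnL2", 1),
    ("nad1", 1), ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1),
    ("trnW", 1), ("trnA", -1), ("trnN", -1), ("trnC", -1), ("trnY", -1),
    ("cox1", 1), ("trnS2", -1), ("trnD", 1), ("cox2", 1), ("trnK", 1),
    ("atp8", 1), ("atp6", 1), ("cox3", 1), ("trnG", 1), ("nad3", 1),
    ("trnR", 1), ("nad4L", 1), ("nad4", 1), ("trnH", 1), ("trnS1", 1),
    ("trnL1", 1), ("nad5", 1), ("nad6", -1), ("trnE", -1), ("cob", 1),
    ("trnT", 1), ("trnP", -1),
])

_marsupial_pairs = list(ANCESTRAL_MAMMAL.genes)
_marsupial_pairs[10:15] = [
    ("trnA", -1), ("trnC", -1), ("trnW", 1), ("trnN", -1), ("trnY", -1),
]
MARSUPIAL = GeneArrangement.from_pairs(_marsupial_pairs)

assert set(ANCESTRAL_MAMMAL.names) == set(ALL_GENES)
assert set(MARSUPIAL.names) == set(ALL_GENES)

#: Marsupial orders among the 304-genome mammalian corpus.
MARSUPIAL_ORDERS = frozenset({
    "Didelphimorphia", "Paucituberculata", "Microbiotheria", "Diprotodontia",
    "Dasyuromorphia", "Notoryctemorphia", "Peramelemorphia",
})


def reference_for(taxon_order: str) -> GeneArrangement:
    """Marsupial reference for marsupial orders, ancestral otherwise."""
    return MARSUPIAL if taxon_order in MARSUPIAL_ORDERS else ANCESTRAL_MAMMAL


# --- encoding ---------------------------------------------------------------

def encode_arrangement(record, anchor: str = "trnF") -> GeneArrangement:
    """Encode a record's annotated gene order as a signed circular permutation.

    Genes are ordered by start coordinate along the circle; CR/OL are
    dropped.  If the anchor gene is absent the arrangement falls back to
    rrnS, then to the lowest-coordinate gene, and a warning is appended to
    the record.
    """
    pairs: list[Signed] = []
    seen: dict[str, object] = {}
    for ann in record.sorted_annotations():
        if ann.name not in ALL_GENES:
            continue
        if ann.name in seen:
            raise DuplicateGeneError(
                f"{record.accession}: duplicate annotation of {ann.name}: "
                f"{seen[ann.name].start}..{seen[ann.name].end} and "
                f"{ann.start}..{ann.end}"
            )
        seen[ann.name] = ann
        pairs.append((ann.name, ann.strand))
    if not pairs:
        raise ValueError(f"{record.accession}: no gene annotations to encode")
    names = {g for g, _ in pairs}
    use_anchor = anchor
    if use_anchor not in names:
        use_anchor = "rrnS" if "rrnS" in names else pairs[0][0]
        record.parse_warnings.append(
            f"anchor {anchor} absent; linearized at {use_anchor}"
        )
    return GeneArrangement.from_pairs(pairs, anchor=use_anchor)


# --- comparison -------------------------------------------------------------

@dataclass(frozen=True)
class ArrangementDiff:
    """Genes whose linearized index or sign differs from the reference."""

    differing: tuple[tuple[str, int, int, int, int], ...]  # (gene, ref idx, obs idx, ref sign, obs sign)

    @property
    def n_differing(self) -> int:
        return len(self.differing)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, *_ in self.differing)


def compare_arrangement(obs: GeneArrangement, ref: GeneArrangement) -> ArrangementDiff:
    """Compare an observed arrangement to a reference.

    Both arrangements are restricted to their common gene set (missing
    genes are the completeness module's concern) and linearized at a
    shared anchor before indices are compared.
    """
    common = set(obs.names) & set(ref.names)
    if not common:
        return ArrangementDiff(())
    o = obs.restricted(common)
    anchor = o.genes[0][0]
    r = ref.restricted(common).rotated_to(anchor)
    oi, ri = o.index(), r.index()
    os_, rs = o.signs, r.signs
    diffs = [
        (g, ri[g], oi[g], rs[g], os_[g])
        for g in r.names
        if oi[g] != ri[g] or os_[g] != rs[g]
    ]
    return ArrangementDiff(tuple(diffs))


def _adjacencies(arr: GeneArrangement) -> set[tuple]:
    """Canonical signed circular adjacencies; (x,y) is identified with (-y,-x)."""
    adj = set()
    genes = arr.genes
    n = len(genes)
    for i in range(n):
        (x, sx), (y, sy) = genes[i], genes[(i + 1) % n]
        a = (x, sx, y, sy)
        b = (y, -sy, x, -sx)
        adj.add(min(a, b))
    return adj


def breakpoint_distance(a: GeneArrangement, b: GeneArrangement) -> int:
    """Number of signed circular adjacencies of ``a`` absent from ``b``."""
    if set(a.names) != set(b.names):
        raise ValueError("breakpoint_distance requires the same gene universe")
    return len(_adjacencies(a) - _adjacencies(b))


# --- single-TDRL reachability ----------------------------------------------

@dataclass(frozen=True)
class TdrlWitness:
    """A tandem duplication/random loss event explaining b from a.

    The ``block`` (contiguous in a, circular) is duplicated in tandem;
    ``lost_from_first`` are deleted from the first copy, ``lost_from_second``
    from the second; together they delete exactly one copy of each gene.
    """

    block: tuple[Signed, ...]
    lost_from_first: tuple[str, ...]
    lost_from_second: tuple[str, ...]


def _split_merge(block: list[str], target: list[str]) -> tuple | None:
    """If target = (subsequence of block) + (complementary subsequence), in
    block order each, return (kept_by_first_copy, kept_by_second_copy)."""
    pos = {g: i for i, g in enumerate(block)}
    k = len(target)
    for cut in range(k + 1):
        first, second = target[:cut], target[cut:]
        fp = [pos[g] for g in first]
        sp = [pos[g] for g in second]
        if all(x < y for x, y in zip(fp, fp[1:])) and all(
            x < y for x, y in zip(sp, sp[1:])
        ):
            return tuple(first), tuple(second)
    return None


def single_tdrl_reachable(
    a: GeneArrangement, b: GeneArrangement
) -> tuple[bool, TdrlWitness | None]:
    """Decide whether ``b`` is one TDRL event away from ``a``.

    True iff ``b`` can be produced from ``a`` by tandemly duplicating one
    contiguous circular block and deleting exactly one copy of each
    duplicated gene.  Signs must be identical (TDRL preserves strand).
    Returns the first (smallest-block) witness found.
    """
    if set(a.names) != set(b.names):
        raise ValueError("single_tdrl_reachable requires the same gene universe")
    if a.signs != b.signs:
        return False, None
    A, B = list(a.names), list(b.names)
    n = len(A)
    if n == 0:
        return True, None
    if n == 1:
        return True, TdrlWitness(tuple(a.genes), (), (A[0],))
    pos_b = {g: i for i, g in enumerate(B)}
    sign = a.signs
    for k in range(1, n + 1):
        for s in range(n):
            block = [A[(s + i) % n] for i in range(k)]
            targets: list[list[str]] = []
            if k < n:
                outside = [A[(s + k + i) % n] for i in range(n - k)]
                j = pos_b[outside[0]]
                if any(B[(j + i) % n] != outside[i] for i in range(n - k)):
                    continue
                targets.append([B[(j + n - k + i) % n] for i in range(k)])
            else:
                targets = [B[r:] + B[:r] for r in range(n)]
            for t in targets:
                split = _split_merge(block, t)
                if split is not None:
                    kept1, kept2 = split
                    return True, TdrlWitness(
                        block=tuple((g, sign[g]) for g in block),
                        lost_from_first=tuple(g for g in block if g not in kept1),
                        lost_from_second=tuple(kept1),
                    )
    return False, None


def apply_tdrl(a: GeneArrangement, witness: TdrlWitness) -> GeneArrangement:
    """Apply a TDRL witness to ``a`` (utility for verifying witnesses)."""
    block_names = [g for g, _ in witness.block]
    n = len(a.names)
    k = len(block_names)
    names = list(a.names)
    # locate the block circularly in a
    start = None
    for s in range(n):
        if all(names[(s + i) % n] == block_names[i] for i in range(k)):
            start = s
            break
    if start is None:
        raise ValueError("witness block is not contiguous in a")
    sign = a.signs
    kept1 = [g for g in block_names if g not in witness.lost_from_first]
    kept2 = [g for g in block_names if g not in witness.lost_from_second]
    if sorted(kept1 + kept2) != sorted(block_names):
        raise ValueError("witness does not delete exactly one copy of each gene")
    outside = [names[(start + k + i) % n] for i in range(n - k)]
    new_names = kept1 + kept2 + outside
    return GeneArrangement.from_pairs(
        [(g, sign[g]) for g in new_names], anchor=a.anchor
    )


# --- compact-notation parsing ----------------------------------------------

_TOKEN_TO_GENE = {v: k for k, v in COMPACT_TOKENS.items()}


def parse_notation(text: str) -> GeneArrangement:
    """Parse the compact arrangement notation, e.g. ``"W-A-N-C-Y"``.

    Tokens are single-letter tRNA codes (with L1/L2/S1/S2 for the
    paralogs), or full gene names (cox1, nad4L, ...); a leading ``-``
    marks minus-strand orientation.
    """
    s = text.strip()
    pairs: list[Signed] = []
    i = 0
    # longest tokens first so e.g. "L1" beats "L" and "nad4L" beats "nad4"
    tokens = sorted(_TOKEN_TO_GENE, key=len, reverse=True)
    while i < len(s):
        if s[i] in " ,":
            i += 1
            continue
        sign = 1
        if s[i] == "-":
            sign = -1
            i += 1
        for tok in tokens:
            if s[i : i + len(tok)] == tok:
                # a bare L/S is ambiguous in this notation; reject it
                if tok in ("L", "S"):
                    raise ValueError(
                        f"ambiguous token {tok!r} in {text!r}: use L1/L2/S1/S2"
                    )
                pairs.append((_TOKEN_TO_GENE[tok], sign))
                i += len(tok)
                break
        else:
            raise ValueError(f"cannot parse arrangement notation at {s[i:]!r}")
    anchor = pairs[0][0] if pairs else "trnF"
    if any(g == "trnF" for g, _ in pairs):
        anchor = "trnF"
    return GeneArrangement.from_pairs(pairs, anchor=anchor)
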