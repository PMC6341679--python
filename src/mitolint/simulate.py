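"""Synthetic mitogenome clades with ground-truth error injection.

The generator emulates the statistical structure the lint checks assume:
a clade of circular ~16.5 kb genomes carrying the full 37-gene mammalian
complement plus control region, with within-clade nucleotide identity
above 90% for conserved genes (per-branch substitution probability 0.05
under a star tree by default), laid out per the ancestral or marsupial
reference arrangement.  Every tRNA is built with an enforced 7-bp
acceptor stem; protein genes start with ATG and contain no internal stop
under the vertebrate mitochondrial code.

Substitutions are i.i.d. uniform over the three alternative bases
(Jukes–Cantor-like), with no rate heterogeneity, transition bias or indel
model — enough to exercise threshold behaviour, not to mimic real codon
evolution.  After mutation each tRNA's acceptor stem is repaired by
overwriting the 3' side with the complement of the 5' side, standing in
for the compensatory substitutions that conserve stems in real tRNAs.

Error injection covers each catalogued annotation-error class; the
returned truth manifest is sufficient to reconstruct the clean records
and to score lint recall.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import findings as F
from .arrangement import ANCESTRAL_MAMMAL, GeneArrangement, MARSUPIAL
from .gene_names import (
    ALL_GENES,
    CONTROL_REGION,
    LIGHT_STRAND_ORIGIN,
    PROTEIN_GENES,
    TRNA_GENES,
)
from .genome_io import GeneAnnotation, MitogenomeRecord, revcomp, write_genbank

# Gene lengths (nt) follow the human mitogenome, rounded to whole codons
# for the protein genes.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp6": 681, "atp8": 207, "cob": 1140, "cox1": 1545, "cox2": 684,
    "cox3": 783, "nad1": 957, "nad2": 1044, "nad3": 348, "nad4": 1377,
    "nad4L": 297, "nad5": 1812, "nad6": 525,
    "rrnS": 950, "rrnL": 1560,
    **{t: 69 for t in TRNA_GENES},
    CONTROL_REGION: 1000,
    LIGHT_STRAND_ORIGIN: 30,
}

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
# Vertebrate mitochondrial code: stops are TAA, TAG, AGA, AGG.
_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _MITO_STOPS
]


@dataclass(frozen=True)
class CladeConfig:
    """Study conditions for one synthetic clade."""

    n_species: int = 8
    taxon_order: str = "Carnivora"
    tree: str = "star"  # "star" or "balanced"
    p_sub: float = 0.05
    arrangement: str = "ancestral"  # "ancestral", "marsupial", or custom below
    custom_arrangement: GeneArrangement | None = None
    gene_lengths: dict[str, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_sub < 0.25):
            raise ValueError("p_sub must be in [0, 0.25)")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.tree not in ("star", "balanced"):
            raise ValueError("tree must be 'star' or 'balanced'")
        if self.arrangement not in ("ancestral", "marsupial", "custom"):
            raise ValueError("arrangement must be ancestral|marsupial|custom")
        if self.arrangement == "custom" and self.custom_arrangement is None:
            raise ValueError("custom arrangement requires custom_arrangement")

    @property
    def reference(self) -> GeneArrangement:
        if self.arrangement == "ancestral":
            return ANCESTRAL_MAMMAL
        if self.arrangement == "marsupial":
            return MARSUPIAL
        return self.custom_arrangement

    @property
    def lengths(self) -> dict[str, int]:
        out = dict(DEFAULT_GENE_LENGTHS)
        if self.gene_lengths:
            out.update(self.gene_lengths)
        return out


@dataclass(frozen=True)
class ErrorInjectionSpec:
    """How many errors of each class to inject into a clade."""

    strand_flips: int = 0
    endpoint_shifts: int = 0
    shift_range: tuple[int, int] = (5, 10)
    deletions: int = 0
    truncations: int = 0
    extensions: int = 0
    extension_range: tuple[int, int] = (25, 40)


@dataclass(frozen=True)
class ManifestEntry:
    accession: str
    gene: str
    error_class: str  # the finding class the injection should provoke
    original: dict | None
    modified: dict | None


@dataclass
class TruthManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def by_class(self, error_class: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.error_class == error_class]

    def to_json(self) -> str:
        return json.dumps(
            [dataclasses.asdict(e) for e in self.entries], indent=2, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls([ManifestEntry(**e) for e in json.loads(text)])

    def __len__(self) -> int:
        return len(self.entries)


def _ann_dict(ann: GeneAnnotation) -> dict:
    return {"start": ann.start, "end": ann.end,
            "strand": "+" if ann.strand > 0 else "-"}


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_trna(n: int, rng: np.random.Generator) -> str:
    # random body with an enforced 7-bp acceptor stem: 3' end pairs 5' end
    core = _random_dna(n, rng)
    return core[: n - 7] + revcomp(core[:7])


def _random_protein(n: int, rng: np.random.Generator) -> str:
    if n % 3:
        raise ValueError("protein gene length must be a codon multiple")
    n_codons = n // 3
    idx = rng.integers(0, len(_SENSE_CODONS), max(n_codons - 2, 0))
    body = "".join(_SENSE_CODONS[i] for i in idx)
    return ("ATG" + body + "TAA")[:n]


def simulate_ancestor(config: CladeConfig, rng: np.random.Generator) -> MitogenomeRecord:
    """Build the clade ancestor laid out per the configured arrangement.

    The genome is linearized at trnF; the control region sits at the end
    of the circle (between trnP and the wrap back to trnF), and the
    light-strand origin between trnN and trnC in the ancestral layout.
    """
    lengths = config.lengths
    layout: list[tuple[str, int]] = []
    arr = config.reference
    names = arr.names
    for i, (gene, sign) in enumerate(arr.genes):
        layout.append((gene, sign))
        nxt = names[(i + 1) % len(names)]
        if gene == "trnN" and nxt == "trnC":
            layout.append((LIGHT_STRAND_ORIGIN, 1))
    layout.append((CONTROL_REGION, 1))

    pieces: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 1
    for gene, sign in layout:
        n = lengths[gene]
        if gene in TRNA_GENES:
            functional = _random_trna(n, rng)
        elif gene in PROTEIN_GENES:
            functional = _random_protein(n, rng)
        else:  # rRNA, CR, OL
            functional = _random_dna(n, rng)
        pieces.append(functional if sign > 0 else revcomp(functional))
        annotations.append(GeneAnnotation(gene, pos, pos + n - 1, sign, gene))
        pos += n

    return MitogenomeRecord(
        accession="ANCESTOR",
        organism=f"{config.taxon_order} ancestor",
        taxon_order=config.taxon_order,
        sequence="".join(pieces),
        annotations=annotations,
    )


def _repair_trna_stems(record: MitogenomeRecord) -> None:
    """Overwrite each tRNA's 3' stem side with the complement of its 5' side."""
    seq = list(record.sequence)
    for ann in record.annotations:
        if ann.name not in TRNA_GENES:
            continue
        if ann.start > ann.end:
            continue  # wrap-around tRNAs are not produced by the simulator
        s, e = ann.start - 1, ann.end  # 0-based half-open
        gene = "".join(seq[s:e])
        if ann.strand < 0:
            gene = revcomp(gene)
        if len(gene) < 14:
            continue
        gene = gene[:-7] + revcomp(gene[:7])
        if ann.strand < 0:
            gene = revcomp(gene)
        seq[s:e] = gene
    record.sequence = "".join(seq)


def evolve(parent: MitogenomeRecord, p_sub: float,
           rng: np.random.Generator) -> MitogenomeRecord:
    """One descendant: i.i.d. substitutions at rate ``p_sub`` per site,
    followed by acceptor-stem repair.  Annotations carry over unchanged."""
    if not (0 <= p_sub < 0.25):
        raise ValueError("p_sub must be in [0, 0.25)")
    idx = np.array([_BASE_IDX.get(c, 4) for c in parent.sequence], dtype=np.int8)
    hit = (rng.random(len(idx)) < p_sub) & (idx < 4)
    idx[hit] = (idx[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    child = parent.copy()
    child.sequence = "".join(
        _BASES[i] if i < 4 else "N" for i in idx
    )
    _repair_trna_stems(child)
    return child


def _evolve_tree(ancestor: MitogenomeRecord, config: CladeConfig,
                 rng: np.random.Generator) -> list[MitogenomeRecord]:
    if config.tree == "star":
        return [evolve(ancestor, config.p_sub, rng) for _ in range(config.n_species)]
    # balanced binary: split lineages, one evolve() per branch
    tips: list[MitogenomeRecord] = []

    def descend(node: MitogenomeRecord, k: int) -> None:
        if k == 1:
            tips.append(evolve(node, config.p_sub, rng))
            return
        left = evolve(node, config.p_sub, rng)
        right = evolve(node, config.p_sub, rng)
        descend(left, k - k // 2)
        descend(right, k // 2)

    descend(ancestor, config.n_species)
    return tips


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def inject_strand_flip(record: MitogenomeRecord, gene: str) -> ManifestEntry:
    """Flip only the annotation's strand field; the sequence is untouched."""
    ann = record.get(gene)
    if ann is None:
        raise ValueError(f"{record.accession} has no annotation of {gene}")
    new = dataclasses.replace(ann, strand=-ann.strand)
    record.annotations[record.annotations.index(ann)] = new
    return ManifestEntry(record.accession, gene, F.STRAND_ERROR,
                         _ann_dict(ann), _ann_dict(new))


def inject_endpoint_shift(record: MitogenomeRecord, gene: str, shift: int,
                          which: str = "end") -> ManifestEntry:
    """Move one endpoint of an annotation by ``shift`` nt (signed)."""
    ann = record.get(gene)
    if ann is None:
        raise ValueError(f"{record.accession} has no annotation of {gene}")
    L = record.length
    if which == "end":
        new = dataclasses.replace(ann, end=ann.end + shift)
    else:
        new = dataclasses.replace(ann, start=ann.start + shift)
    if not (1 <= new.start <= L and 1 <= new.end <= L) or new.start > new.end:
        raise ValueError(f"shift pushes {gene} outside the genome")
    record.annotations[record.annotations.index(ann)] = new
    return ManifestEntry(record.accession, gene, F.ENDPOINT_ERROR,
                         _ann_dict(ann), _ann_dict(new))


def inject_deletion(record: MitogenomeRecord, gene: str) -> ManifestEntry:
    """Remove an annotation; the gene sequence remains in place."""
    ann = record.get(gene)
    if ann is None:
        raise ValueError(f"{record.accession} has no annotation of {gene}")
    record.annotations.remove(ann)
    return ManifestEntry(record.accession, gene, F.MISSING_ANNOTATION,
                         _ann_dict(ann), None)


def inject_extension(record: MitogenomeRecord, gene: str, extra: int) -> ManifestEntry:
    """Over-extend a tRNA's 3' end into the downstream sequence."""
    ann = record.get(gene)
    if ann is None:
        raise ValueError(f"{record.accession} has no annotation of {gene}")
    if ann.strand > 0:
        new = dataclasses.replace(ann, end=ann.end + extra)
    else:
        new = dataclasses.replace(ann, start=ann.start - extra)
    L = record.length
    if not (1 <= new.start <= L and 1 <= new.end <= L):
        raise ValueError(f"extension pushes {gene} outside the genome")
    record.annotations[record.annotations.index(ann)] = new
    return ManifestEntry(record.accession, gene, F.LONG_GENE,
                         _ann_dict(ann), _ann_dict(new))


def inject_cr_truncation(record: MitogenomeRecord,
                         rng: np.random.Generator) -> ManifestEntry:
    """Delete sequence from trnP's interior through trnF's interior.

    Mimics an incompletely sequenced record: the control region vanishes,
    both flanking tRNAs are left truncated, and all coordinates shift while
    the record still claims to be complete.
    """
    trnF, trnP = record.get("trnF"), record.get("trnP")
    cr = record.get(CONTROL_REGION)
    if trnF is None or trnP is None or cr is None:
        raise ValueError(f"{record.accession}: truncation needs trnF, trnP and CR")
    if not (trnF.start < trnP.start <= trnP.end <= cr.start - 1 or trnP.end < cr.start):
        pass  # layout check is advisory; simulator layout guarantees order
    L = record.length
    keep_f = int(rng.integers(20, 41))  # nt of trnF retained
    keep_p = int(rng.integers(20, 41))  # nt of trnP retained
    cut_f = trnF.start + keep_f  # first retained position (1-based)
    cut_p = trnP.start + keep_p - 1  # last retained position

    new_seq = record.sequence[cut_f - 1 : cut_p]
    shift = cut_f - 1
    new_annotations: list[GeneAnnotation] = []
    for ann in record.annotations:
        if ann.name == CONTROL_REGION:
            continue
        if ann.name == "trnF":
            new_annotations.append(
                dataclasses.replace(ann, start=1, end=trnF.end - cut_f + 1)
            )
        elif ann.name == "trnP":
            new_annotations.append(
                dataclasses.replace(ann, start=ann.start - shift, end=cut_p - shift)
            )
        else:
            new_annotations.append(
                dataclasses.replace(ann, start=ann.start - shift, end=ann.end - shift)
            )
    original = _ann_dict(cr)
    record.sequence = new_seq
    record.annotations = new_annotations
    return ManifestEntry(record.accession, CONTROL_REGION, F.MISSING_SEQUENCE,
                         original, None)


# ---------------------------------------------------------------------------
# clade generation
# ---------------------------------------------------------------------------

class InfeasibleInjection(ValueError):
    pass


def generate_clade(
    config: CladeConfig,
    injection: ErrorInjectionSpec | None = None,
    seed: int | None = None,
) -> tuple[list[MitogenomeRecord], TruthManifest]:
    """Simulate a clade and optionally inject annotation errors.

    Injection targets are drawn without overlap: within each class every
    targeted gene label is distinct across the whole clade, trnF and trnP
    are reserved for the truncation class, and no (record, gene) pair
    receives two injections.  This keeps every injected error assessable
    against clean orthologs, matching the idiosyncratic, one-off character
    of real submission errors.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    ancestor = simulate_ancestor(config, rng)
    records = _evolve_tree(ancestor, config, rng)
    prefix = (config.taxon_order[:3].upper() or "SYN")
    for i, rec in enumerate(records, 1):
        rec.accession = f"{prefix}{i:03d}"
        rec.organism = f"{config.taxon_order} synthetic sp. {i}"

    manifest = TruthManifest()
    if injection is None:
        return records, manifest

    spec = injection
    rng_inj = np.random.default_rng(rng.integers(0, 2**31 - 1))
    used_pairs: set[tuple[str, str]] = set()

    def pick_records(k: int) -> list[int]:
        if k > len(records):
            raise InfeasibleInjection("more truncations than records")
        return list(rng_inj.choice(len(records), size=k, replace=False))

    # truncations first: they rewrite sequence and coordinates
    for ri in pick_records(spec.truncations):
        manifest.entries.append(inject_cr_truncation(records[ri], rng_inj))
        used_pairs.update({(records[ri].accession, g) for g in ("trnF", "trnP", CONTROL_REGION)})

    reserved = {"trnF", "trnP"}
    trna_pool = [g for g in TRNA_GENES if g not in reserved]
    gene_pool = [g for g in ALL_GENES if g not in reserved]

    def sample_genes(pool: list[str], k: int, label: str) -> list[str]:
        if k > len(pool):
            raise InfeasibleInjection(
                f"cannot place {k} {label} on {len(pool)} available genes"
            )
        return [pool[i] for i in rng_inj.choice(len(pool), size=k, replace=False)]

    shift_genes = sample_genes(trna_pool, spec.endpoint_shifts, "endpoint shifts")
    ext_pool = [g for g in trna_pool if g not in shift_genes]
    ext_genes = sample_genes(ext_pool, spec.extensions, "extensions")
    del_pool = [g for g in gene_pool if g not in shift_genes and g not in ext_genes]
    del_genes = sample_genes(del_pool, spec.deletions, "deletions")
    flip_pool = [g for g in gene_pool if g not in shift_genes
                 and g not in ext_genes and g not in del_genes]
    flip_genes = sample_genes(flip_pool, spec.strand_flips, "strand flips")

    def place(gene: str) -> MitogenomeRecord:
        order = rng_inj.permutation(len(records))
        for ri in order:
            rec = records[ri]
            if (rec.accession, gene) in used_pairs:
                continue
            if rec.get(gene) is None:
                continue
            used_pairs.add((rec.accession, gene))
            return rec
        raise InfeasibleInjection(f"no record available for injection on {gene}")

    for gene in flip_genes:
        manifest.entries.append(inject_strand_flip(place(gene), gene))
    for gene in shift_genes:
        lo, hi = spec.shift_range
        shift = int(rng_inj.integers(lo, hi + 1)) * (1 if rng_inj.random() < 0.5 else -1)
        which = "end" if rng_inj.random() < 0.5 else "start"
        manifest.entries.append(inject_endpoint_shift(place(gene), gene, shift, which))
    for gene in del_genes:
        manifest.entries.append(inject_deletion(place(gene), gene))
    for gene in ext_genes:
        lo, hi = spec.extension_range
        manifest.entries.append(
            inject_extension(place(gene), gene, int(rng_inj.integers(lo, hi + 1)))
        )
    return records, manifest


# ---------------------------------------------------------------------------
# corpus output
# ---------------------------------------------------------------------------

def write_clade(records: list[MitogenomeRecord], manifest: TruthManifest,
                outdir: str | Path) -> None:
    """One GenBank file per species plus ``truth_manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_genbank(rec, outdir / f"{rec.accession}.gb")
    (outdir / "truth_manifest.json").write_text(manifest.to_json() + "\n")


def load_manifest(path: str | Path) -> TruthManifest:
    return TruthManifest.from_json(Path(path).read_text())
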