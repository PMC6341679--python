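# Methods

## The two-reference model

The package encodes a strong prior about mammalian mitogenomes: one gene
complement (13 protein-coding genes, 2 rRNAs, 22 tRNAs, plus the control
region and, in eutherians/monotremes, the light-strand origin OL between
trnN and trnC) and exactly two genuine gene orders. The ancestral
arrangement (anchored at trnF) is

```
F rrnS V rrnL L2 nad1 I -Q M nad2 W -A -N -C -Y cox1 -S2 D cox2 K atp8
atp6 cox3 G nad3 R nad4L nad4 H S1 L1 nad5 -nad6 -E cob T -P
```

and the marsupial arrangement replaces the WANCY block `W -A -N -C -Y`
with `-A -C W -N -Y`; every other position and every strand is identical.
Deviation from the applicable reference is therefore not evidence of a
rearrangement event until the sequence supports it — which is the whole
premise of the lint.

Arrangements are signed circular permutations over the 37 gene
identifiers; CR and OL are excluded (they are non-gene features missing
from many records, and per-order accounting counts genes only). A record
is linearized at trnF, falling back to rrnS and then to the
lowest-coordinate gene when the anchor is unannotated (the record is
flagged). "Genes differing" counts each gene whose linearized index *or*
sign differs from the reference, each gene once; with this convention a
marsupial record diffed against the ancestral reference yields exactly
4 differing genes (W, A, N, C — trnY keeps both index and sign).

## Single-TDRL reachability

A tandem duplication/random loss event duplicates one contiguous circular
block in tandem and then deletes exactly one copy of each duplicated gene
(no partial retention); strand is untouched. Arrangement `b` is one event
from `a` iff, for some circular block of `a`, the remainder of `a` appears
unchanged in `b` and the block region of `b` splits into two disjoint
subsequences, each in block order — the genes kept from the first and the
second copy respectively. The search scans blocks in increasing length
and returns the first witness, so `a = b` is explained by duplicating a
single gene and dropping one copy, and the ancestral→marsupial WANCY
transition is explained by duplicating `W -A -N -C` and losing W,N from
the first copy and A,C from the second. Any sign change short-circuits to
unreachable. Complexity is O(n⁴) for n genes — trivial at n = 37 — and
the implementation is tested exhaustively against a brute-force move
enumerator (all blocks × all 2^k loss patterns) for all signed
arrangements over ≤ 5 genes, plus samples at n = 6.

Breakpoint distance is the number of signed circular adjacencies of one
arrangement absent from the other, with (x, y) identified with (−y, −x);
it is reported as a summary statistic only.

## Orientation verification

The operative criterion is the 80% rule: a gene extracted *as annotated*
is globally aligned against orthologs from close relatives in both
orientations. Scoring is linear (match +1, mismatch −1, gap −2) via
Biopython's `PairwiseAligner`; identity is computed by this package as
identical A/C/G/T columns divided by all columns between the first and
last aligned pair. Stripping terminal gap columns is deliberate: an
annotation with a wrong endpoint is length-discordant with its ortholog,
and terminal gaps would otherwise dilute identity and mask the
orientation signal. N never counts as identical. The verdict table:
forward ≥ τ and strictly greater than reverse-complement → CONFIRMED;
reverse-complement ≥ τ and strictly greater → STRAND_ERROR; an exact
forward/reverse tie (e.g. a palindrome) or both below τ → UNRESOLVED.
A tie against the threshold itself (identity exactly τ) resolves in favor
of the annotation under test.

Ortholog donors are drawn from records sharing the query's taxonomic
order (falling back to the whole corpus), ranked by identity of the
conserved anchor gene cox1, capped at 3. One further constraint matters:
a donor's annotation of the gene under test must itself conform in strand
to the donor's own reference arrangement, with non-conforming donors used
only when no conforming donor exists. Without it, two records carrying
the same wrong-strand annotation would confirm each other — the situation
actually arises when a clade contains several copies of the same
submission error (e.g. four of six dasyuromorph records annotated with a
spurious -IQ inversion).

## tRNA structure check

Only the 7-bp amino-acyl acceptor stem is scored: position i (1..7)
against position L−i+1, Watson–Crick or G·U wobble, N never pairs. The
D- and T-arms of mitochondrial tRNAs are too degenerate for a cloverleaf
heuristic, and a covariance-model tRNA finder is out of scope; the
acceptor stem is the element diagnostic of correct endpoints. Note one
asymmetry: Watson–Crick pairing between the two ends is exactly preserved
under reverse complement, but a G·U pair maps to A·C and is lost, so the
default stem score is only revcomp-invariant up to the number of wobble
pairs (the test suite asserts the exact invariance for the WC-only mode).

Thresholds: length bounds 55/90 nt (mammalian mt-tRNAs run ~59–75 nt;
the bounds are deliberately loose because real flagged cases are grossly
aberrant), minimum stem 5/7, ortholog length tolerance 10 nt. With stems
enforced at 7/7 by the generator, a shifted annotation window pairs
randomly: the chance a random register still scores ≥ 5/7 is ≈ 7%
(Binomial(7, 0.375)), which bounds the per-shift miss rate of the
endpoint check; measured recall on ≥ 5 nt shifts is ~0.9–1.0.

## Completeness

Missing annotations are recovered syntenically: for every unannotated gap
≥ 30 nt (excluding the CR locus between trnP and trnF and the OL locus
between trnN and trnC), the nearest flanking *genes* determine which
reference genes are expected inside, and the gap is aligned against
neighbor orthologs of each expected gene in both orientations under the
same 0.80 rule; a hit reports coordinates and strand. Genes that are
neither annotated nor recoverable are reported as not present.

The control region is held to a 0.50 identity standard instead — the CR
evolves fast enough that even congeneric D-loops can drop toward ~57%
identity, so the 0.80 gene rule would systematically miss real CRs. CR
length is the annotated span or, failing that, the unassigned
nucleotides between trnP and trnF. MISSING_SEQUENCE requires either a
zero-length CR or a short CR (< 200 nt) corroborated by a truncated or
absent flanking tRNA (trnT, trnP, trnF); an unusually short CR with
intact flankers is tolerated, since short CRs can be real. A ≥ 200 nt
span with no CR feature is CR_UNANNOTATED.

## Synthetic clades

The generator builds the study conditions the checks assume. A clade
ancestor is laid out per the chosen reference: tRNAs 69 nt with an
enforced 7-bp acceptor stem, rRNAs 950/1,560 nt, proteins at human-like
codon-multiple lengths starting ATG with no internal stop under the
vertebrate mitochondrial code, CR 1,000 nt, OL 30 nt — ~16.4 kb total.
Descendants evolve by i.i.d. uniform substitutions (Jukes–Cantor-like; no
rate heterogeneity, transition bias, or indels) at p_sub = 0.05 per
branch under a star tree by default, giving ~90% pairwise identity —
the conserved-gene similarity regime observed within real mammalian
clades. After mutation each tRNA's 3′ stem side is overwritten with the
complement of its 5′ side, a stand-in for the compensatory substitutions
that conserve stems in nature; it keeps the structure check exercisable
at any divergence.

Error injection covers five classes: strand flips (annotation strand
only; sequence untouched), single-endpoint shifts of 5–10 nt on tRNAs,
annotation deletions, 3′ over-extensions of tRNAs, and control-region
truncations that delete from trnP's interior through trnF's interior and
re-coordinate the record while leaving it declared complete. Within each
class, targets use globally distinct gene labels, trnF/trnP are reserved
for truncations, and no (record, gene) pair is hit twice — mirroring the
idiosyncratic, one-off character of real submission errors and keeping
every injected error assessable against clean orthologs. The truth
manifest lists each injection with its original and modified annotation.

What the generator does *not* emulate — indel evolution, compositional
strand bias, duplicated or overlapping genes, heterogeneous gene lengths
across taxa, sequencing noise — bounds what passing tests show: they
validate the decision logic and thresholds under the similarity structure
the method assumes, not performance on raw database records.

## Numerical and procedural choices

- Coordinates are 1-based inclusive throughout (GenBank convention);
  start > end encodes a feature wrapping the circular origin.
- Ambiguous `tRNA-Leu`/`tRNA-Ser` labels (no codon-family qualifier) are
  resolved by syntenic position (between rrnL and nad1 → trnL2; after
  cox1 → trnS2; after trnH → trnS1; after trnS1 → trnL1); unresolvable
  copies are dropped with a warning.
- When a locus carries both a `gene` and a `CDS`/`tRNA`/`rRNA` feature,
  they merge into one annotation and the specific feature's coordinates
  win.
- Identity values are those of the first optimal alignment the aligner
  yields; co-optimal alignments can differ in identity by small amounts,
  which is one reason reported identities may differ slightly from
  figures produced with multiple-alignment software.
- UNRESOLVED verdicts (conflicting or absent ortholog evidence) are
  reported but excluded from confirmed/refuted tallies.
- Reports are sorted by accession, then genome coordinate; identical
  inputs and configuration produce byte-identical output, and simulated
  GenBank files carry a fixed date stamp for the same reason.

## Problem sizes

The shipped study uses clades of 4–12 species (22 marsupial-like records
across three orders, plus an 8-species eutherian-like clade carrying 38
injected errors and its clean twin), exhaustive TDRL validation over ≤ 5
genes with sampling at 6, and 200-pair oracle checks for alignment and
breakpoint kernels. These sizes exercise every code path and keep the
whole suite and the acceptance script in the tens of seconds.

## Known limitations

- The stem heuristic misses ~7% of endpoint shifts whose shifted window
  pairs by chance; it also cannot locate the *correct* endpoints, only
  flag suspects.
- Orientation verdicts inherit the corpus: a gene flipped in every
  available relative cannot be refuted from sequence alone.
- The gap scanner assumes the reference gene order to predict gap
  contents, so a genuinely novel rearrangement combined with a missing
  annotation may scan against the wrong expected gene and return no
  candidate rather than a wrong one.
- Real GenBank feature tables are diverse; the synonym table covers the
  common label families (tested on constructed fixtures), not every
  submitter idiosyncrasy.
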