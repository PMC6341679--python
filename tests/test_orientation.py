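"""Both-orientation verification and alignment identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolint import (
    VerificationConfig,
    choose_neighbors,
    extract_gene_sequence,
    global_align_identity,
    revcomp,
    verify_orientation,
)
from oracles import nw_optimal_identity_range

DNA = st.text(alphabet="ACGT", min_size=4, max_size=40)


class TestIdentity:
    def test_self_identity_is_one(self):
        seq = "ACGT" * 17 + "A"  # 69 nt
        assert global_align_identity(seq, seq) == 1.0

    def test_two_mismatches_over_69(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), 69))
        query = list(ref)
        query[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[query[10]]
        query[40] = {"A": "G", "C": "T", "G": "A", "T": "C"}[query[40]]
        assert global_align_identity("".join(query), ref) == pytest.approx(67 / 69)

    def test_dissimilar_4mers(self):
        assert global_align_identity("ACGT", "TTTT") <= 0.25
        # brute-force confirms the gap-free alignment is optimal
        score, lo, hi = nw_optimal_identity_range("ACGT", "TTTT")
        assert score == -2 and hi <= 0.25

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align_identity("", "ACGT")

    def test_n_bases_never_identical(self):
        assert global_align_identity("ANNNA", "ANNNA") == pytest.approx(2 / 5)

    @given(DNA, DNA)
    @settings(max_examples=60, derandomize=True)
    def test_matches_needleman_wunsch_oracle(self, q, r):
        ident = global_align_identity(q, r)
        score, lo, hi = nw_optimal_identity_range(q, r)
        assert lo - 1e-12 <= ident <= hi + 1e-12
        assert 0.0 <= ident <= 1.0


class TestVerdicts:
    def test_identical_sequence_confirmed(self):
        seq = "ATGCCGTAAGGCTAAGCTTACGGATCGATCGGGTACCATG"
        v = verify_orientation(seq, [seq], gene="trnW")
        assert v.verdict == "CONFIRMED"
        assert v.identity_fwd == 1.0

    def test_reverse_complement_is_strand_error(self):
        seq = "ATGCCGTAAGGCTAAGCTTACGGATCGATCGGGTACCATG"
        v = verify_orientation(revcomp(seq), [seq])
        assert v.verdict == "STRAND_ERROR"

    def test_unrelated_sequences_unresolved(self):
        v = verify_orientation("A" * 40, ["GC" * 20])
        assert v.verdict == "UNRESOLVED"

    def test_exact_tie_above_threshold_unresolved(self):
        palindrome = "ACGT" * 10  # its reverse complement equals itself
        v = verify_orientation(palindrome, [palindrome])
        assert v.identity_fwd == v.identity_rc == 1.0
        assert v.verdict == "UNRESOLVED"

    def test_empty_neighbor_list_rejected(self):
        with pytest.raises(ValueError):
            verify_orientation("ACGT", [])

    @given(st.text(alphabet="ACGT", min_size=20, max_size=40),
           st.text(alphabet="ACGT", min_size=20, max_size=40))
    @settings(max_examples=40, derandomize=True)
    def test_never_confirmed_in_both_orientations(self, s, r):
        v1 = verify_orientation(s, [r])
        v2 = verify_orientation(revcomp(s), [r])
        assert not (v1.verdict == "CONFIRMED" and v2.verdict == "CONFIRMED")


class TestAotusLikeScenario:
    """Congeners at ~98% identity; one record annotated on the wrong strand."""

    def test_wrong_strand_wancy_trna_refuted(self, clean_clade):
        import dataclasses

        records = [r.copy() for r in clean_clade]
        bad = records[0]
        for gene in ("trnW", "trnA", "trnN", "trnC", "trnY"):
            ann = bad.get(gene)
            bad.annotations[bad.annotations.index(ann)] = dataclasses.replace(
                ann, strand=-ann.strand
            )
        for gene in ("trnW", "trnA", "trnN", "trnC", "trnY"):
            seq = extract_gene_sequence(bad, bad.get(gene))
            neighbors = choose_neighbors(bad, records, gene)
            v = verify_orientation(seq, neighbors, gene=gene)
            assert v.verdict == "STRAND_ERROR", gene


class TestChooseNeighbors:
    def test_ranked_by_cox1_identity_and_capped(self, clean_clade):
        neighbors = choose_neighbors(clean_clade[0], clean_clade, "trnW")
        assert 1 <= len(neighbors) <= 3
        assert clean_clade[0].accession not in [a for a, _ in neighbors]

    def test_lone_record_yields_no_neighbors(self, clean_clade):
        assert choose_neighbors(clean_clade[0], [clean_clade[0]], "trnW") == []

    def test_same_order_preferred(self, clean_clade, marsupial_clade):
        corpus = list(clean_clade) + list(marsupial_clade)
        neighbors = choose_neighbors(clean_clade[0], corpus, "cob")
        donor_orders = {
            r.taxon_order for r in corpus
            if r.accession in {a for a, _ in neighbors}
        }
        assert donor_orders == {"Carnivora"}


def test_clean_clade_confirms_every_gene(clean_clade):
    """At ~10% pairwise divergence every annotation clears tau=0.80."""
    config = VerificationConfig()
    record = clean_clade[0]
    for ann in record.annotations:
        if ann.name in ("CR", "OL"):
            continue
        neighbors = choose_neighbors(record, clean_clade, ann.name, config)
        v = verify_orientation(
            extract_gene_sequence(record, ann), neighbors, config, gene=ann.name
        )
        assert v.verdict == "CONFIRMED", (ann.name, v)
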