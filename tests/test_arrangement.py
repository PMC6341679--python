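"""Signed gene orders: encoding, comparison, breakpoints, TDRL."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolint import (
    ANCESTRAL_MAMMAL,
    GeneArrangement,
    MARSUPIAL,
    apply_tdrl,
    breakpoint_distance,
    compare_arrangement,
    encode_arrangement,
    parse_notation,
    single_tdrl_reachable,
)
from mitolint.arrangement import DuplicateGeneError
from oracles import (
    all_single_tdrl_results,
    breakpoints_by_enumeration,
    circular_canon,
)


def _arr(pairs, anchor=None):
    return GeneArrangement.from_pairs(pairs, anchor=anchor or pairs[0][0])


class TestReferences:
    def test_references_cover_37_genes(self):
        assert len(ANCESTRAL_MAMMAL) == len(MARSUPIAL) == 37

    def test_marsupial_differs_only_in_wancy(self):
        diff = compare_arrangement(MARSUPIAL, ANCESTRAL_MAMMAL)
        assert diff.n_differing == 4
        assert set(diff.genes) == {"trnW", "trnA", "trnN", "trnC"}

    def test_marsupial_wancy_notation(self):
        block = GeneArrangement.from_pairs(MARSUPIAL.genes[10:15], anchor="trnA")
        assert block.notation() == "-A-CW-N-Y"
        block = GeneArrangement.from_pairs(ANCESTRAL_MAMMAL.genes[10:15], anchor="trnW")
        assert block.notation() == "W-A-N-C-Y"


class TestEncode:
    def test_clean_record_matches_reference(self, clean_clade):
        assert encode_arrangement(clean_clade[0]).genes == ANCESTRAL_MAMMAL.genes

    def test_single_sign_perturbation(self, clean_clade):
        record = clean_clade[0].copy()
        ann = record.get("trnA")
        record.annotations[record.annotations.index(ann)] = dataclasses.replace(
            ann, strand=1
        )
        diff = compare_arrangement(encode_arrangement(record), ANCESTRAL_MAMMAL)
        assert diff.genes == ("trnA",)

    def test_rotation_invariance(self, clean_clade):
        """Rotating the genome mid-cox1 must not change the arrangement."""
        record = clean_clade[0]
        L = record.length
        offset = record.get("cox1").start + 500  # cut inside cox1
        rotated = record.copy()
        rotated.sequence = record.sequence[offset:] + record.sequence[:offset]

        def shift(pos):
            return (pos - offset - 1) % L + 1

        rotated.annotations = [
            dataclasses.replace(a, start=shift(a.start), end=shift(a.end))
            for a in record.annotations
        ]
        assert encode_arrangement(rotated).genes == encode_arrangement(record).genes

    def test_duplicate_gene_errors(self, clean_clade):
        record = clean_clade[0].copy()
        record.annotations = record.annotations + [
            dataclasses.replace(record.get("trnW"), start=16000, end=16060)
        ]
        with pytest.raises(DuplicateGeneError, match="trnW"):
            encode_arrangement(record)


class TestCompare:
    def test_identity_has_no_differences(self):
        assert compare_arrangement(ANCESTRAL_MAMMAL, ANCESTRAL_MAMMAL).n_differing == 0

    def test_iq_double_inversion_counts_two(self):
        pairs = list(ANCESTRAL_MAMMAL.genes)
        i_q = {g: i for i, (g, _) in enumerate(pairs)}
        pairs[i_q["trnI"]] = ("trnI", -1)
        pairs[i_q["trnQ"]] = ("trnQ", 1)
        diff = compare_arrangement(_arr(pairs, "trnF"), ANCESTRAL_MAMMAL)
        assert set(diff.genes) == {"trnI", "trnQ"}


class TestBreakpoints:
    def test_identical_arrangements_have_zero(self):
        assert breakpoint_distance(MARSUPIAL, MARSUPIAL) == 0

    def test_wancy_block_has_five_breakpoints(self):
        """Within nad2..cox1 only the -Y/cox1 (and wrap) adjacency survives."""
        anc = GeneArrangement.from_pairs(ANCESTRAL_MAMMAL.genes[9:16], anchor="nad2")
        mar = GeneArrangement.from_pairs(MARSUPIAL.genes[9:16], anchor="nad2")
        assert breakpoint_distance(anc, mar) == 5
        assert breakpoint_distance(anc, mar) == breakpoints_by_enumeration(
            anc.genes, mar.genes
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, derandomize=True)
    def test_symmetric_and_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"g{i}" for i in range(rng.integers(3, 9))]
        def random_arr():
            perm = rng.permutation(len(names))
            return _arr([(names[i], int(rng.choice([1, -1]))) for i in perm])
        a, b = random_arr(), random_arr()
        d_ab, d_ba = breakpoint_distance(a, b), breakpoint_distance(b, a)
        assert d_ab == d_ba
        assert d_ab == breakpoints_by_enumeration(a.genes, b.genes)


class TestTdrl:
    def test_identity_is_trivially_reachable(self):
        ok, witness = single_tdrl_reachable(ANCESTRAL_MAMMAL, ANCESTRAL_MAMMAL)
        assert ok
        assert apply_tdrl(ANCESTRAL_MAMMAL, witness).genes == ANCESTRAL_MAMMAL.genes

    def test_sign_flip_is_never_reachable(self):
        pairs = list(ANCESTRAL_MAMMAL.genes)
        pairs[10] = (pairs[10][0], -pairs[10][1])
        assert single_tdrl_reachable(ANCESTRAL_MAMMAL, _arr(pairs, "trnF"))[0] is False

    def test_wancy_marsupial_transition(self):
        """The marsupial WANCY order is one duplication/loss event from the
        ancestral order, via duplication of W -A -N -C."""
        ok, witness = single_tdrl_reachable(ANCESTRAL_MAMMAL, MARSUPIAL)
        assert ok
        assert [g for g, _ in witness.block] == ["trnW", "trnA", "trnN", "trnC"]
        assert set(witness.lost_from_first) == {"trnW", "trnN"}
        assert set(witness.lost_from_second) == {"trnA", "trnC"}
        assert apply_tdrl(ANCESTRAL_MAMMAL, witness).genes == MARSUPIAL.genes

    def test_wancy_block_alone(self):
        a = _arr([("trnW", 1), ("trnA", -1), ("trnN", -1), ("trnC", -1), ("trnY", -1)])
        b = _arr([("trnA", -1), ("trnC", -1), ("trnW", 1), ("trnN", -1), ("trnY", -1)])
        ok, witness = single_tdrl_reachable(a, b)
        assert ok
        assert circular_canon(apply_tdrl(a, witness).genes) == circular_canon(b.genes)

    def test_exhaustive_agreement_with_oracle_n4(self):
        names = ["g0", "g1", "g2", "g3"]
        a = _arr([(g, 1) for g in names])
        reachable = all_single_tdrl_results(a.genes)
        from itertools import permutations, product
        n_checked = 0
        for perm in permutations(names):
            for signs in product((1, -1), repeat=4):
                b = _arr(list(zip(perm, signs)), anchor=perm[0])
                expected = circular_canon(b.genes) in reachable
                got, witness = single_tdrl_reachable(a, b)
                assert got == expected, (perm, signs)
                if got:
                    assert circular_canon(apply_tdrl(a, witness).genes) == \
                        circular_canon(b.genes)
                n_checked += 1
        assert n_checked == 24 * 16


def test_notation_parse_round_trip():
    arr = parse_notation("W-A-N-C-Y")
    assert arr.genes == (("trnW", 1), ("trnA", -1), ("trnN", -1),
                         ("trnC", -1), ("trnY", -1))
    assert parse_notation(MARSUPIAL.notation()).genes == MARSUPIAL.genes
    assert parse_notation(ANCESTRAL_MAMMAL.notation()).genes == ANCESTRAL_MAMMAL.genes
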