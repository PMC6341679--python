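"""The synthetic clade generator: construction invariants and injections."""

import numpy as np
import pytest

from mitolint import (
    ANCESTRAL_MAMMAL,
    CladeConfig,
    ErrorInjectionSpec,
    MARSUPIAL,
    acceptor_stem_score,
    encode_arrangement,
    evolve,
    extract_gene_sequence,
    generate_clade,
    simulate_ancestor,
    single_tdrl_reachable,
)
from mitolint.gene_names import PROTEIN_GENES, TRNA_GENES
from mitolint.simulate import InfeasibleInjection

_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}


class TestAncestor:
    def test_ancestral_layout_encodes_reference(self):
        rng = np.random.default_rng(0)
        anc = simulate_ancestor(CladeConfig(), rng)
        assert encode_arrangement(anc).genes == ANCESTRAL_MAMMAL.genes
        assert 15000 < anc.length < 18000

    def test_marsupial_layout_and_tdrl(self):
        rng = np.random.default_rng(0)
        anc = simulate_ancestor(CladeConfig(arrangement="marsupial"), rng)
        arr = encode_arrangement(anc)
        assert arr.genes == MARSUPIAL.genes
        assert single_tdrl_reachable(ANCESTRAL_MAMMAL, arr)[0]

    def test_trnas_have_perfect_stems(self):
        rng = np.random.default_rng(1)
        anc = simulate_ancestor(CladeConfig(), rng)
        for ann in anc.annotations:
            if ann.name in TRNA_GENES:
                assert acceptor_stem_score(extract_gene_sequence(anc, ann)) == 7

    def test_proteins_start_atg_and_lack_internal_stops(self):
        rng = np.random.default_rng(2)
        anc = simulate_ancestor(CladeConfig(), rng)
        for gene in PROTEIN_GENES:
            seq = extract_gene_sequence(anc, anc.get(gene))
            assert seq.startswith("ATG")
            codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            assert not any(c in _MITO_STOPS for c in codons)

    def test_deterministic_given_seed(self):
        a = simulate_ancestor(CladeConfig(), np.random.default_rng(9))
        b = simulate_ancestor(CladeConfig(), np.random.default_rng(9))
        assert a.sequence == b.sequence and a.annotations == b.annotations


class TestEvolve:
    def test_zero_rate_is_identity(self):
        anc = simulate_ancestor(CladeConfig(), np.random.default_rng(3))
        child = evolve(anc, 0.0, np.random.default_rng(4))
        assert child.sequence == anc.sequence

    def test_divergence_matches_binomial_expectation(self):
        """p=0.05 on nad5 (1812 nt): identity within 3 binomial sd of 95%,
        comparing outside the repaired tRNA stems."""
        anc = simulate_ancestor(CladeConfig(), np.random.default_rng(5))
        child = evolve(anc, 0.05, np.random.default_rng(6))
        a = extract_gene_sequence(anc, anc.get("nad5"))
        c = extract_gene_sequence(child, child.get("nad5"))
        frac = sum(x == y for x, y in zip(a, c)) / len(a)
        p_same = 0.95
        sd = (p_same * (1 - p_same) / len(a)) ** 0.5
        assert abs(frac - p_same) < 3 * sd

    def test_stems_repaired_after_mutation(self):
        anc = simulate_ancestor(CladeConfig(), np.random.default_rng(7))
        child = evolve(anc, 0.10, np.random.default_rng(8))
        for ann in child.annotations:
            if ann.name in TRNA_GENES:
                assert acceptor_stem_score(extract_gene_sequence(child, ann)) == 7

    def test_annotations_carried_over(self):
        anc = simulate_ancestor(CladeConfig(), np.random.default_rng(7))
        child = evolve(anc, 0.05, np.random.default_rng(8))
        assert child.annotations == anc.annotations


class TestGenerateClade:
    def test_no_injection_empty_manifest(self, clean_clade):
        # fixture built with no injection spec; accessions are deterministic
        assert [r.accession for r in clean_clade] == [
            "CAR001", "CAR002", "CAR003", "CAR004"
        ]

    def test_reproducible_end_to_end(self):
        cfg = CladeConfig(n_species=3)
        spec = ErrorInjectionSpec(strand_flips=2, deletions=1)
        r1, m1 = generate_clade(cfg, spec, seed=13)
        r2, m2 = generate_clade(cfg, spec, seed=13)
        assert m1.entries == m2.entries
        assert all(a.sequence == b.sequence and a.annotations == b.annotations
                   for a, b in zip(r1, r2))

    def test_manifest_counts_match_spec(self):
        cfg = CladeConfig(n_species=8)
        spec = ErrorInjectionSpec(strand_flips=5, endpoint_shifts=4,
                                  deletions=3, truncations=2, extensions=1)
        records, manifest = generate_clade(cfg, spec, seed=21)
        classes = [e.error_class for e in manifest.entries]
        assert classes.count("STRAND_ERROR") == 5
        assert classes.count("ENDPOINT_ERROR") == 4
        assert classes.count("MISSING_ANNOTATION") == 3
        assert classes.count("MISSING_SEQUENCE") == 2
        assert classes.count("LONG_GENE") == 1

    def test_injections_never_share_a_record_gene_pair(self):
        cfg = CladeConfig(n_species=8)
        spec = ErrorInjectionSpec(strand_flips=20, endpoint_shifts=10,
                                  deletions=5, truncations=3)
        _, manifest = generate_clade(cfg, spec, seed=23)
        pairs = [(e.accession, e.gene) for e in manifest.entries]
        assert len(pairs) == len(set(pairs)) == 38

    def test_strand_flip_leaves_sequence_untouched(self):
        cfg = CladeConfig(n_species=2)
        clean, _ = generate_clade(cfg, seed=17)
        flipped, manifest = generate_clade(cfg, ErrorInjectionSpec(strand_flips=1),
                                           seed=17)
        assert [r.sequence for r in clean] == [r.sequence for r in flipped]
        entry = manifest.entries[0]
        assert entry.original["strand"] != entry.modified["strand"]

    def test_truncation_shortens_genome_and_drops_cr(self):
        cfg = CladeConfig(n_species=2)
        clean, _ = generate_clade(cfg, seed=19)
        cut, manifest = generate_clade(cfg, ErrorInjectionSpec(truncations=1),
                                       seed=19)
        entry = manifest.entries[0]
        damaged = next(r for r in cut if r.accession == entry.accession)
        pristine = next(r for r in clean if r.accession == entry.accession)
        assert damaged.length < pristine.length - 900  # CR (1000 nt) mostly gone
        assert damaged.get("CR") is None
        assert damaged.get("trnF").length(damaged.length) < 55
        assert damaged.get("trnP").length(damaged.length) < 55

    def test_infeasible_counts_rejected(self):
        with pytest.raises(InfeasibleInjection):
            generate_clade(CladeConfig(n_species=2),
                           ErrorInjectionSpec(truncations=5), seed=1)
        with pytest.raises(InfeasibleInjection):
            generate_clade(CladeConfig(n_species=2),
                           ErrorInjectionSpec(endpoint_shifts=25), seed=1)

    def test_balanced_tree_divergence(self):
        cfg = CladeConfig(n_species=4, tree="balanced", p_sub=0.02)
        records, _ = generate_clade(cfg, seed=29)
        assert len(records) == 4
        assert len({r.sequence for r in records}) == 4
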