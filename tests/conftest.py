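"""Shared fixtures: synthetic clades and a handcrafted GenBank file."""

from __future__ import annotations



import pytest

from mitolint import CladeConfig, LintConfig, generate_clade

CLEAN_SEED = 42
INJECT_SEED = 11


@pytest.fixture(scope="session")
def clean_clade():
    """Four eutherian-like species, ancestral arrangement, ~10% pairwise div."""
    records, manifest = generate_clade(
        CladeConfig(n_species=4, taxon_order="Carnivora", p_sub=0.05),
        seed=CLEAN_SEED,
    )
    assert len(manifest) == 0
    return records


@pytest.fixture(scope="session")
def marsupial_clade():
    """Four marsupial-like species (Didelphimorphia label)."""
    records, _ = generate_clade(
        CladeConfig(n_species=4, taxon_order="Didelphimorphia",
                    arrangement="marsupial", p_sub=0.05),
        seed=CLEAN_SEED,
    )
    return records


@pytest.fixture(scope="session")
def lint_config():
    return LintConfig()


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        spaced = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {spaced}")
    return "\n".join(lines)


@pytest.fixture()
def handcrafted_genbank(tmp_path):
    """A foreign-style record: gene+CDS pair, ambiguous tRNA-Leu, synonymous
    D-loop label, an unmappable feature.  Synthetic fixture, not a real
    accession."""
    seq = "acgt" * 125
    header = """\
LOCUS       TEST0001                 500 bp    DNA     circular MAM 15-SEP-2017
DEFINITION  Testus fictus mitochondrion, complete genome.
ACCESSION   TEST0001
VERSION     TEST0001.1
SOURCE      mitochondrion Testus fictus
  ORGANISM  Testus fictus
            Eukaryota; Metazoa; Mammalia; Carnivora; Testidae.
FEATURES             Location/Qualifiers
     source          1..500
                     /organism="Testus fictus"
                     /organelle="mitochondrion"
     rRNA            1..100
                     /product="16S ribosomal RNA"
     tRNA            101..169
                     /product="tRNA-Leu"
     gene            170..281
                     /gene="ND1"
     CDS             171..280
                     /gene="ND1"
     tRNA            complement(282..350)
                     /product="tRNA-Ala"
     misc_feature    351..360
                     /note="mystery palindrome"
     D-loop          361..480
                     /note="A+T-rich region"
ORIGIN
"""
    text = header + _origin_block(seq) + "\n//\n"
    path = tmp_path / "handcrafted.gb"
    path.write_text(text)
    return path
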