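#!/usr/bin/env python
"""Generate the synthetic study corpora.

Three marsupial-like clades sized after the three largest marsupial orders
of the mammalian mitogenome survey (Didelphimorphia 4, Diprotodontia 12,
Dasyuromorphia 6, the latter with the spurious -IQ double inversion
injected into 4 records), plus one eutherian-like clade carrying injected
errors of every class and its uninjected twin.  Writes GenBank corpora and
truth manifests under scratch/corpus/.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mitolint import CladeConfig, ErrorInjectionSpec, generate_clade, write_clade
from mitolint.simulate import TruthManifest, inject_strand_flip

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "scratch" / "corpus"


def main() -> None:
    marsupial_orders = [
        ("Didelphimorphia", 4, 0, 101),
        ("Diprotodontia", 12, 0, 211),
        ("Dasyuromorphia", 6, 4, 307),
    ]
    for order, n, n_iq, offset in marsupial_orders:
        records, manifest = generate_clade(
            CladeConfig(n_species=n, taxon_order=order, arrangement="marsupial",
                        p_sub=0.05),
            seed=SEED + offset,
        )
        for r in records[:n_iq]:
            manifest.entries.append(inject_strand_flip(r, "trnI"))
            manifest.entries.append(inject_strand_flip(r, "trnQ"))
        write_clade(records, manifest, OUT / order.lower())
        print(f"{order}: {n} records"
              + (f", {2 * n_iq} injected I/Q strand flips" if n_iq else ""))

    config = CladeConfig(n_species=8, taxon_order="Carnivora", p_sub=0.05)
    spec = ErrorInjectionSpec(strand_flips=20, endpoint_shifts=10,
                              shift_range=(5, 10), deletions=5, truncations=3)
    records, manifest = generate_clade(config, spec, seed=SEED)
    write_clade(records, manifest, OUT / "carnivora_injected")
    print(f"Carnivora (injected): 8 records, {len(manifest)} injected errors")

    clean, _ = generate_clade(config, seed=SEED)
    write_clade(clean, TruthManifest(), OUT / "carnivora_clean")
    print("Carnivora (clean): 8 records, 0 injected errors")
    print(f"corpora written under {OUT}")


if __name__ == "__main__":
    main()
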