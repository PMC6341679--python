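#!/usr/bin/env python
"""Characterize the ancestral-to-marsupial WANCY rearrangement.

Shows that the two mammalian gene orders differ in exactly four genes,
computes their breakpoint distance, and derives the single tandem
duplication/random loss event that converts W -A -N -C -Y into
-A -C W -N -Y.  Writes results/wancy_tdrl.txt.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mitolint import (
    ANCESTRAL_MAMMAL,
    MARSUPIAL,
    apply_tdrl,
    breakpoint_distance,
    compare_arrangement,
    single_tdrl_reachable,
)
from mitolint.gene_names import COMPACT_TOKENS

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _fmt(pairs) -> str:
    return "".join(("-" if s < 0 else "") + COMPACT_TOKENS.get(g, g)
                   for g, s in pairs)


def main() -> None:
    lines = []
    diff = compare_arrangement(MARSUPIAL, ANCESTRAL_MAMMAL)
    lines.append("Ancestral (monotreme/eutherian) WANCY block: "
                 + _fmt(ANCESTRAL_MAMMAL.genes[10:15]))
    lines.append("Marsupial WANCY block:                       "
                 + _fmt(MARSUPIAL.genes[10:15]))
    lines.append(f"Genes differing between the two references: "
                 f"{diff.n_differing} ({', '.join(diff.genes)})")
    lines.append(f"Breakpoint distance (full 37-gene circles): "
                 f"{breakpoint_distance(ANCESTRAL_MAMMAL, MARSUPIAL)}")

    ok, witness = single_tdrl_reachable(ANCESTRAL_MAMMAL, MARSUPIAL)
    assert ok and witness is not None
    lines.append("")
    lines.append("Single tandem duplication/random loss event:")
    lines.append(f"  duplicated block: {_fmt(witness.block)}")
    lines.append(f"  lost from first copy:  {', '.join(witness.lost_from_first)}")
    lines.append(f"  lost from second copy: {', '.join(witness.lost_from_second)}")
    result = apply_tdrl(ANCESTRAL_MAMMAL, witness)
    lines.append(f"  applying the event reproduces the marsupial order: "
                 f"{result.genes == MARSUPIAL.genes}")
    lines.append("")
    lines.append("A sign-changing rearrangement (an inversion) is never one")
    lines.append("TDRL away: the model duplicates and deletes but preserves")
    lines.append("strand, which is why wrong-strand annotations masquerade as")
    lines.append("novel rearrangement events until they are refuted.")

    text = "\n".join(lines) + "\n"
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "wancy_tdrl.txt").write_text(text)
    print(text, end="")


if __name__ == "__main__":
    main()
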