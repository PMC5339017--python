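"""Cloning-oligo generation for annealed-oligo (BbsI-style) insertion.

Designs are RNA; synthesis orders are DNA. The insert (back-fold + loop +
spacer, never the scaffold) is transliterated U->T, optionally prefixed
with the G required at +1 by the U6 promoter, and flanked with the 4-nt
overhangs left single-stranded after annealing: CACC on the top strand and
AAAC on the bottom strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grammar import SBHConstruct, apply_u6_g
from .sequences import revcomp_dna, rna_to_dna

TOP_OVERHANG = "CACC"
BOTTOM_OVERHANG = "AAAC"


@dataclass(frozen=True)
class OligoPair:
    """Top/bottom synthesis oligos for one insert."""

    top: str
    bottom: str
    overhang_top: str = TOP_OVERHANG
    overhang_bottom: str = BOTTOM_OVERHANG

    @property
    def insert(self) -> str:
        return self.top[len(self.overhang_top):]


def oligos_for_insert(insert_dna: str, enforce_g1: bool = False) -> OligoPair:
    """Oligo pair for a raw DNA insert; bit-exact by construction."""
    if not insert_dna:
        raise ValueError("empty insert")
    if enforce_g1:
        insert_dna = apply_u6_g(insert_dna)  # the +G1 rule is alphabet-agnostic
    return OligoPair(
        top=TOP_OVERHANG + insert_dna,
        bottom=BOTTOM_OVERHANG + revcomp_dna(insert_dna),
    )


def cloning_oligos(construct: SBHConstruct, enforce_g1: bool = True) -> OligoPair:
    """Annealed-oligo pair for a construct's back-fold-loop-spacer insert."""
    insert_rna = construct.hairpin_sequence
    if not insert_rna:
        raise ValueError("construct has an empty insert")
    if enforce_g1:
        insert_rna = apply_u6_g(insert_rna)
    return oligos_for_insert(rna_to_dna(insert_rna), enforce_g1=False)
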