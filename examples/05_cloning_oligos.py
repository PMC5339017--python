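"""Generate annealed cloning oligos for an SBH guide.

The back-fold-loop-spacer insert is transliterated to DNA, prefixed with
the G required at +1 for U6-promoter transcription, and flanked with the
CACC / AAAC overhangs that remain single-stranded after annealing, ready
for ligation into a BbsI-linearized guide backbone.
"""

from sbhdesign import (
    DEFAULT_0B_PATTERN,
    SpacerRecord,
    assemble_sbh,
    cloning_oligos,
)

spacer = SpacerRecord("demo", "AUGGCUGAGUGGAUCGACAA")
construct = assemble_sbh(spacer, bulge_pattern=DEFAULT_0B_PATTERN)
pair = cloning_oligos(construct, enforce_g1=True)

print("insert (RNA):", construct.hairpin_sequence)
print("top oligo   :", pair.top)
print("bottom oligo:", pair.bottom)
print("\nAnnealing the two oligos leaves exactly the 4-nt CACC/AAAC")
print("overhangs single-stranded; the bottom strand is the reverse")
print("complement of the insert.")
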