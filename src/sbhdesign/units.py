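"""Cleaving units, loop elements and scaffold constants.

A cleaving unit is the interchangeable element that replaces the basic
hairpin loop and turns a silent SBH guide into an inducible one: an
endoribonuclease recognition motif (Csy4, Cas6A), a self-cleaving ribozyme,
or an ASO-sensing loop. Each unit may carry a cut site (cleavage occurs 5'
of ``cut_offset``) and an internal pairing scheme used when building the
expected secondary structure of the assembled guide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import normalize_rna

GraftMode = str  # "apex" | "distal_bulge" | "proximal_bulge"
GRAFT_MODES = ("apex", "distal_bulge", "proximal_bulge")


@dataclass(frozen=True)
class CleavingUnit:
    """A graftable RNA element: sensing loop, nuclease motif or ribozyme.

    ``cut_offset`` is the 0-based position within the unit 5' of which
    cleavage occurs (``None`` for non-cleavable loops). ``internal_pairs``
    are 0-based (i, j) pairs internal to the unit, included in the expected
    fold of any construct carrying it.
    """

    name: str
    sequence: str
    cut_offset: int | None = None
    graft_mode: GraftMode = "apex"
    internal_pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.graft_mode not in GRAFT_MODES:
            raise ValueError(f"unknown graft mode {self.graft_mode!r}")
        if self.cut_offset is not None and not 0 <= self.cut_offset <= len(self.sequence):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(self.sequence)}]"
            )
        for i, j in self.internal_pairs:
            if not (0 <= i < j < len(self.sequence)):
                raise ValueError(f"internal pair ({i}, {j}) outside the unit")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)

    @property
    def tail_length(self) -> int:
        """Nucleotides retained 3' of the cut site (0 when not cleavable)."""
        if self.cut_offset is None:
            return 0
        return len(self.sequence) - self.cut_offset


# The minimal tetraloop used for non-inducible SBH guides. The prototype
# loop of the original constructs is a configurable alternative; GAAA is a
# stable, structurally inert default.
BASIC_LOOP = CleavingUnit(name="basic_loop", sequence="GAAA")

#: Degenerate "no loop" element for native-guide edge cases.
NO_LOOP = CleavingUnit(name="none", sequence="")

# P. aeruginosa Csy4 recognition element: the canonical 28-nt CRISPR repeat.
# The enzyme clamps the 5-bp stem-loop (positions 5-9 paired with 15-19) and
# cleaves 3' of G20, so processed downstream RNA keeps an 8-nt 5' tag.
CSY4 = CleavingUnit(
    name="Csy4",
    sequence="GUUCACUGCCGUAUAGGCAGCUAAGAAA",
    cut_offset=20,
    internal_pairs=((5, 19), (6, 18), (7, 17), (8, 16), (9, 15)),
)

# T. thermophilus Cas6A element. Synthetic stand-in: a 28-nt hairpin with
# the same layout as the Csy4 repeat (5-bp stem, cleavage 3' of the stem,
# 8-nt retained tag) but unrelated sequence, so orthogonality demos behave
# sensibly. Replace with the experimentally validated motif for real designs.
CAS6A = CleavingUnit(
    name="Cas6A",
    sequence="GCCAAAGAGGACUGAAAGUCCUAGUGCC",
    cut_offset=20,
    internal_pairs=((5, 19), (6, 18), (7, 17), (8, 16), (9, 15)),
)

# Hammerhead-ribozyme unit. Synthetic stand-in hairpin marking where a
# self-cleaving HHRz would graft; the catalytic sequence itself is supplied
# by the user (the ribozyme is handled purely as a graftable unit).
HHRZ = CleavingUnit(
    name="HHRz",
    sequence="GGGAUGUCCGGUAUCCCAUAGGACGAAA",
    cut_offset=24,
    internal_pairs=((0, 17), (1, 16), (2, 15), (3, 14), (4, 13)),
)

UNIT_CATALOG: dict[str, CleavingUnit] = {
    u.name: u for u in (BASIC_LOOP, NO_LOOP, CSY4, CAS6A, HHRZ)
}

# Standard S. pyogenes tracrRNA scaffold appended 3' of the spacer.
TRACR_SCAFFOLD = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGG"
    "CACCGAGUCGGUGCUUUU"
)

# SAM-style scaffold carrying two MS2 aptamers (tetraloop + stem-loop 2),
# selectable for guides that recruit MCP-fused effectors.
SAM_SCAFFOLD = (
    "GUUUUAGAGCUAGGCCAACAUGAGGAUCACCCAUGUCUGCAGGGCCUAGCAAGUUAAAAUAA"
    "GGCUAGUCCGUUAUCAACUUGGCCAACAUGAGGAUCACCCAUGUCUGCAGGGCCAAGUGGCA"
    "CCGAGUCGGUGCUUUU"
)

SCAFFOLDS: dict[str, str] = {"tracr": TRACR_SCAFFOLD, "sam": SAM_SCAFFOLD}
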