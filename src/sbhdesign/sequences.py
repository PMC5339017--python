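"""Nucleotide-alphabet primitives shared across the package.

All design logic operates on uppercase RNA (A/C/G/U). DNA is accepted at
ingestion (T transliterated to U) and re-emitted only for synthesis oligos.
"""

from __future__ import annotations

RNA_BASES = "ACGU"
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains a character outside the expected alphabet."""


def normalize_rna(seq: str) -> str:
    """Uppercase and transliterate DNA->RNA (T->U); reject anything else.

    Raises :class:`AlphabetError` naming the first offending position.
    """
    out = seq.strip().upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in RNA_BASES:
            raise AlphabetError(f"invalid nucleotide {ch!r} at position {i}")
    return out


def revcomp_rna(seq: str) -> str:
    """Reverse complement under A<->U, C<->G. Involutive."""
    for i, ch in enumerate(seq):
        if ch not in RNA_BASES:
            raise AlphabetError(f"invalid nucleotide {ch!r} at position {i}")
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G)."""
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise AlphabetError(f"invalid nucleotide {ch!r} at position {i}")
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    """Transliterate an RNA design into the DNA string ordered for synthesis."""
    return seq.replace("U", "T")


def is_watson_crick(a: str, b: str) -> bool:
    """True when the two RNA bases form a canonical A:U or G:C pair."""
    return b == a.translate(_RNA_COMPLEMENT)


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; 0.0 for the empty string."""
    if not seq:
        return 0.0
    return sum(1 for ch in seq if ch in "GC") / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical consecutive nucleotides."""
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def pairs_from_dotbracket(structure: str) -> dict[int, int]:
    """Map every paired position to its partner (both directions, 0-based).

    Only nested '(' / ')' / '.' strings are accepted; pseudoknot alphabets
    are out of scope for this design grammar.
    """
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise ValueError(f"unexpected structure character {ch!r} at {i}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return pairs
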